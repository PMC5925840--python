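"""Positional statistics for intron groups along the gene body axis."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PositionSample:
    """A labelled set of gene-body fractions in [0, 1]."""

    label: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size == 0:
            raise ValueError(f"position sample {self.label!r} is empty")
        if ((self.positions < 0) | (self.positions > 1)).any():
            raise ValueError(f"positions of {self.label!r} must lie in [0, 1]")

    @property
    def n(self) -> int:
        return int(self.positions.size)


def ks_location_test(
    sample_up: PositionSample, sample_down: PositionSample
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Uses the exact null distribution when both samples have n <= 25 and the
    asymptotic one otherwise.
    """
    method = "exact" if (sample_up.n <= 25 and sample_down.n <= 25) else "asymp"
    res = stats.ks_2samp(
        sample_up.positions, sample_down.positions, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def ecdf_curves(samples: Sequence[PositionSample]) -> dict[str, pd.DataFrame]:
    """Step-function ECDF per sample, evaluated at the observed positions."""
    out = {}
    for s in samples:
        x = np.sort(s.positions)
        y = np.arange(1, x.size + 1) / x.size
        out[s.label] = pd.DataFrame({"position": x, "ecdf": y})
    return out


def position_histogram(sample: PositionSample, n_bins: int = 20) -> pd.DataFrame:
    """Equal-width density histogram over [0, 1]."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    density, edges = np.histogram(sample.positions, bins=n_bins, range=(0.0, 1.0), density=True)
    counts, _ = np.histogram(sample.positions, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "count": counts,
            "density": density,
        }
    )


def ks_results_table(pairs: dict[str, tuple[PositionSample, PositionSample]]) -> pd.DataFrame:
    """KS test table for labelled sample pairs (for TSV export)."""
    rows = []
    for name, (up, down) in pairs.items():
        d, p = ks_location_test(up, down)
        rows.append(
            {"comparison": name, "n_up": up.n, "n_down": down.n, "D": d, "p_value": p}
        )
    return pd.DataFrame(rows)
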