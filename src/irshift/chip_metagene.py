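"""Metagene binning of ChIP coverage and promoter-proximal shift calls.

Each gene longer than the bin count is summarised as a 500-bin vector: 100
bins over the 2-kb upstream flank, 300 over the gene body and 100 over the
2-kb downstream flank, oriented TSS to TTS. Coverage is scaled to a
10-million-read library and calibrated against the matched input (signed
difference by default, log2 ratio behind a flag). A gene is shift-called
when at least 30% of the front half of its body bins gained signal while at
least 30% of the rear half lost signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import GeneModel, IntronUnit
from .quantification import AlignmentSet


@dataclass(frozen=True)
class BinLayout:
    n_body: int = 300
    n_flank: int = 100
    flank_bp: int = 2000

    @property
    def n_total(self) -> int:
        return self.n_body + 2 * self.n_flank

    def body_slice(self) -> slice:
        return slice(self.n_flank, self.n_flank + self.n_body)


DEFAULT_LAYOUT = BinLayout()

Calibration = Literal["difference", "log2ratio", "none"]


class ShortGeneError(ValueError):
    """Gene body too short for the bin layout."""


@dataclass
class BinProfile:
    gene_id: str
    bins: np.ndarray
    mark: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)


def _bin_means(cov: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean per-base coverage in ``n_bins`` equal (possibly fractional) bins."""
    length = len(cov)
    cum = np.concatenate([[0.0], np.cumsum(cov)])
    edges = np.linspace(0.0, length, n_bins + 1)
    integrals = np.interp(edges, np.arange(length + 1), cum)
    widths = np.diff(edges)
    return np.diff(integrals) / widths


def _raw_profile(
    alignments: AlignmentSet, gene: GeneModel, layout: BinLayout
) -> np.ndarray:
    """Unnormalised mean-coverage bins in genomic orientation."""
    up = gene.span_start - layout.flank_bp
    cov_left = alignments.coverage(gene.chrom, up, gene.span_start)
    cov_body = alignments.coverage(gene.chrom, gene.span_start, gene.span_end)
    cov_right = alignments.coverage(gene.chrom, gene.span_end, gene.span_end + layout.flank_bp)
    return np.concatenate(
        [
            _bin_means(cov_left, layout.n_flank),
            _bin_means(cov_body, layout.n_body),
            _bin_means(cov_right, layout.n_flank),
        ]
    )


def bin_coverage(
    chip_alignments: AlignmentSet,
    input_alignments: Optional[AlignmentSet],
    gene: GeneModel,
    layout: BinLayout = DEFAULT_LAYOUT,
    calibration: Calibration = "difference",
    norm_reads: float = 1e7,
    pseudocount: float = 0.5,
    mark: str = "",
) -> BinProfile:
    """Normalised, input-calibrated 500-bin profile for one gene.

    Raises :class:`ShortGeneError` for genes whose body is not longer than
    ``layout.n_body + 2 * layout.n_flank`` bp, and ``ValueError`` when
    calibration is requested without an input library.
    """
    if gene.length <= layout.n_total:
        raise ShortGeneError(
            f"gene {gene.gene_id}: body {gene.length} bp <= {layout.n_total} bp"
        )
    if calibration != "none" and input_alignments is None:
        raise ValueError("input control required for calibration")
    if chip_alignments.n_reads <= 0:
        raise ValueError("ChIP library size must be positive")

    chip = _raw_profile(chip_alignments, gene, layout) * (norm_reads / chip_alignments.n_reads)
    if calibration == "none":
        bins = chip
    else:
        if input_alignments.n_reads <= 0:
            raise ValueError("input library size must be positive")
        inp = _raw_profile(input_alignments, gene, layout) * (
            norm_reads / input_alignments.n_reads
        )
        if calibration == "difference":
            bins = chip - inp
        elif calibration == "log2ratio":
            bins = np.log2(chip + pseudocount) - np.log2(inp + pseudocount)
        else:
            raise ValueError(f"unknown calibration {calibration!r}")
    if gene.strand == "-":
        bins = bins[::-1]
    return BinProfile(gene.gene_id, bins, mark=mark, sample_id=chip_alignments.sample_id)


def profile_genes(
    chip_alignments: AlignmentSet,
    input_alignments: Optional[AlignmentSet],
    genes: Iterable[GeneModel],
    layout: BinLayout = DEFAULT_LAYOUT,
    **kw,
) -> tuple[dict[str, BinProfile], dict[str, str]]:
    """Profiles keyed by gene, plus per-gene exclusion reasons."""
    profiles: dict[str, BinProfile] = {}
    excluded: dict[str, str] = {}
    for g in genes:
        try:
            profiles[g.gene_id] = bin_coverage(
                chip_alignments, input_alignments, g, layout, **kw
            )
        except ShortGeneError as exc:
            excluded[g.gene_id] = str(exc)
    return profiles, excluded


def aggregate_profile(profiles: Iterable[BinProfile]) -> tuple[np.ndarray, int]:
    """Element-wise mean across genes and the gene count."""
    mats = [p.bins for p in profiles]
    if not mats:
        raise ValueError("no profiles to aggregate")
    return np.mean(mats, axis=0), len(mats)


@dataclass
class DiffMatrix:
    gene_order: list[str]
    matrix: np.ndarray
    sort_keys: np.ndarray
    layout: BinLayout = field(default_factory=BinLayout)

    def row(self, gene_id: str) -> np.ndarray:
        return self.matrix[self.gene_order.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.gene_order)
        df.insert(0, "sort_key", self.sort_keys)
        df.index.name = "gene_id"
        return df


def diff_matrix(
    profiles_mut: Mapping[str, BinProfile],
    profiles_wt: Mapping[str, BinProfile],
    layout: BinLayout = DEFAULT_LAYOUT,
) -> DiffMatrix:
    """Mutant-minus-WT matrix, rows sorted by descending count of positive
    ("red") gene-body bins, ties broken by gene id."""
    sym_diff = set(profiles_mut) ^ set(profiles_wt)
    if sym_diff:
        raise ValueError(
            "gene sets differ between conditions: " + ", ".join(sorted(sym_diff))
        )
    body = layout.body_slice()
    rows = []
    for gid in profiles_mut:
        diff = profiles_mut[gid].bins - profiles_wt[gid].bins
        rows.append((gid, diff, int(np.sum(diff[body] > 0))))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return DiffMatrix(
        gene_order=[r[0] for r in rows],
        matrix=np.vstack([r[1] for r in rows]) if rows else np.empty((0, layout.n_total)),
        sort_keys=np.array([r[2] for r in rows], dtype=int),
        layout=layout,
    )


def call_shift(
    diff_row: np.ndarray,
    layout: BinLayout = DEFAULT_LAYOUT,
    min_fraction: float = 0.30,
) -> bool:
    """Promoter-proximal shift rule on one mutant-minus-WT row.

    Shifted iff >= ``min_fraction`` of the front half of the body bins have a
    strictly positive difference and >= ``min_fraction`` of the rear half a
    strictly negative one. Flank bins are ignored; zeros count to neither
    side.
    """
    diff_row = np.asarray(diff_row, dtype=float)
    if len(diff_row) != layout.n_total:
        raise ValueError(
            f"expected {layout.n_total} bins, got {len(diff_row)}"
        )
    body = diff_row[layout.body_slice()]
    half = layout.n_body // 2
    need = int(np.ceil(min_fraction * half))
    front_pos = int(np.sum(body[:half] > 0))
    rear_neg = int(np.sum(body[half:] < 0))
    return front_pos >= need and rear_neg >= need


@dataclass(frozen=True)
class ShiftCall:
    gene_id: str
    me2_shifted: bool
    me3_shifted: bool

    @property
    def type(self) -> str:
        if self.me2_shifted and self.me3_shifted:
            return "III"
        if self.me2_shifted:
            return "I"
        if self.me3_shifted:
            return "II"
        return "IV"


def classify_shift_types(
    me2_calls: Mapping[str, bool], me3_calls: Mapping[str, bool]
) -> list[ShiftCall]:
    """Type I (me2 only) / II (me3 only) / III (both) / IV (neither)."""
    if set(me2_calls) != set(me3_calls):
        raise ValueError("me2 and me3 call sets cover different genes")
    return [
        ShiftCall(gid, bool(me2_calls[gid]), bool(me3_calls[gid]))
        for gid in sorted(me2_calls)
    ]


def shift_calls_frame(calls: Sequence[ShiftCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "me2_shifted": c.me2_shifted,
                "me3_shifted": c.me3_shifted,
                "type": c.type,
            }
            for c in calls
        ]
    )


def signal_at_introns(
    chip_alignments: AlignmentSet,
    input_alignments: Optional[AlignmentSet],
    intron_groups: Mapping[str, Sequence[IntronUnit]],
    norm_reads: float = 1e7,
) -> dict:
    """Mean calibrated coverage per intron, grouped, with Welch tests.

    Empty groups are an error. Returns per-group value arrays, medians and
    pairwise p-values.
    """
    chip_scale = norm_reads / chip_alignments.n_reads
    inp_scale = (
        norm_reads / input_alignments.n_reads if input_alignments is not None else 0.0
    )
    values: dict[str, np.ndarray] = {}
    for label, introns in intron_groups.items():
        if len(introns) == 0:
            raise ValueError(f"intron group {label!r} is empty")
        vals = []
        for u in introns:
            cov = chip_alignments.coverage(u.chrom, u.start, u.end).mean() * chip_scale
            if input_alignments is not None:
                cov -= input_alignments.coverage(u.chrom, u.start, u.end).mean() * inp_scale
            vals.append(cov)
        values[label] = np.asarray(vals)

    tests = {}
    labels = sorted(values)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            if len(values[la]) < 2 or len(values[lb]) < 2 or (
                np.ptp(values[la]) == 0 and np.ptp(values[lb]) == 0
            ):
                tests[(la, lb)] = float("nan") if len(values[la]) < 2 else 1.0
            else:
                tests[(la, lb)] = float(
                    stats.ttest_ind(values[la], values[lb], equal_var=False).pvalue
                )
    return {
        "values": values,
        "medians": {k: float(np.median(v)) for k, v in values.items()},
        "p_values": tests,
    }


def signal_expression_association(
    gene_signal: Mapping[str, float],
    gene_fpkm: Mapping[str, float],
    n_quantiles: int = 5,
) -> dict:
    """Mean signal per expression quantile plus Spearman correlation."""
    genes = sorted(set(gene_signal) & set(gene_fpkm))
    if len(genes) < n_quantiles:
        raise ValueError("fewer genes than quantiles")
    sig = np.array([gene_signal[g] for g in genes], dtype=float)
    expr = np.array([gene_fpkm[g] for g in genes], dtype=float)
    if np.ptp(sig) == 0 or np.ptp(expr) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = stats.spearmanr(expr, sig)
    order = np.argsort(np.argsort(expr, kind="stable"), kind="stable")
    q = np.minimum((order * n_quantiles) // len(genes), n_quantiles - 1)
    per_q = pd.DataFrame(
        {
            "quantile": np.arange(n_quantiles),
            "mean_signal": [float(sig[q == i].mean()) for i in range(n_quantiles)],
            "mean_fpkm": [float(expr[q == i].mean()) for i in range(n_quantiles)],
            "n": [int((q == i).sum()) for i in range(n_quantiles)],
        }
    )
    return {"per_quantile": per_q, "spearman_rho": float(rho), "p_value": float(p)}
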