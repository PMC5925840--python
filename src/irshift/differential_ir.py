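"""Differential intron-retention calls between two conditions.

Calls are fold-change based: replicate-averaged retention indices are
compared with a pseudocount-stabilised ratio, gated by read-support,
length-coverage and expression filters evaluated in the condition asserting
the higher retention (configurable to both conditions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Thresholds:
    """Filter block for differential-IR calling."""

    min_reads: float = 3.0
    min_coverage: float = 0.8
    min_gene_fpkm: float = 1.0
    min_flank_fpkm: float = 1.0
    fold: float = 2.0
    epsilon: float = 0.01
    filter_scope: Literal["higher", "both"] = "higher"

    def with_(self, **kw) -> "Thresholds":
        return replace(self, **kw)


DEFAULT_THRESHOLDS = Thresholds()

_AVG_COLS = [
    "iri",
    "supporting_reads",
    "length_coverage",
    "gene_fpkm",
    "flank_left_fpkm",
    "flank_right_fpkm",
    "flank_mean_fpkm",
]


def _average_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    if not tables:
        raise ValueError("at least one replicate table required")
    cat = pd.concat(tables, ignore_index=True)
    keep = ["intron_id", "gene_id", "rel_position"] + _AVG_COLS
    grouped = cat[keep].groupby(["intron_id", "gene_id", "rel_position"], as_index=False).mean()
    return grouped


def _passes(row: pd.Series, suffix: str, t: Thresholds) -> bool:
    return bool(
        row[f"supporting_reads{suffix}"] >= t.min_reads
        and row[f"length_coverage{suffix}"] >= t.min_coverage
        and row[f"gene_fpkm{suffix}"] >= t.min_gene_fpkm
        and row[f"flank_left_fpkm{suffix}"] > t.min_flank_fpkm
        and row[f"flank_right_fpkm{suffix}"] > t.min_flank_fpkm
    )


def call_differential_ir(
    tables_a: Sequence[pd.DataFrame],
    tables_b: Sequence[pd.DataFrame],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-intron differential-retention table (condition b vs a).

    Columns: averaged ``iri_a``/``iri_b``, pseudocount ratio
    ``(iri_b + eps) / (iri_a + eps)``, ``filters_passed`` and ``direction``
    in {up, down, unchanged}. ``up`` requires ratio >= fold and the filter
    block to pass; ``down`` the reciprocal.
    """
    a = _average_replicates(tables_a)
    b = _average_replicates(tables_b)
    m = a.merge(b, on=["intron_id", "gene_id", "rel_position"], suffixes=("_a", "_b"))
    if m.empty:
        raise ValueError("empty intersection of intron unit sets between conditions")

    eps = thresholds.epsilon
    iri_a = m["iri_a"].fillna(0.0).to_numpy()
    iri_b = m["iri_b"].fillna(0.0).to_numpy()
    ratio = (iri_b + eps) / (iri_a + eps)

    passed = np.empty(len(m), dtype=bool)
    for i, (_, row) in enumerate(m.iterrows()):
        pa = _passes(row, "_a", thresholds)
        pb = _passes(row, "_b", thresholds)
        if thresholds.filter_scope == "both":
            passed[i] = pa and pb
        else:  # evaluate in the condition asserting retention
            passed[i] = pb if iri_b[i] >= iri_a[i] else pa

    direction = np.where(
        passed & (ratio >= thresholds.fold),
        "up",
        np.where(passed & (ratio <= 1.0 / thresholds.fold), "down", "unchanged"),
    )
    out = m[["intron_id", "gene_id", "rel_position"]].copy()
    out["iri_a"] = iri_a
    out["iri_b"] = iri_b
    out["ratio"] = ratio
    out["filters_passed"] = passed
    out["direction"] = direction
    return out


def classify_genes(diff_records: pd.DataFrame) -> pd.DataFrame:
    """Partition genes into up_only / down_only / both / none."""
    rows = []
    for gene_id, grp in diff_records.groupby("gene_id"):
        n_up = int((grp["direction"] == "up").sum())
        n_down = int((grp["direction"] == "down").sum())
        if n_up and n_down:
            cls = "both"
        elif n_up:
            cls = "up_only"
        elif n_down:
            cls = "down_only"
        else:
            cls = "none"
        rows.append({"gene_id": gene_id, "class": cls, "n_up": n_up, "n_down": n_down})
    return pd.DataFrame(rows, columns=["gene_id", "class", "n_up", "n_down"])


def compare_expression_by_class(
    classes: pd.DataFrame,
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    pseudocount: float = 1.0,
) -> dict:
    """log2 expression fold changes per gene class plus pairwise Welch tests.

    ``fpkm_a``/``fpkm_b`` carry gene_id and fpkm columns (replicates may be
    stacked; they are averaged per gene). Classes with fewer than two genes
    are skipped and flagged.
    """
    fa = fpkm_a.groupby("gene_id")["fpkm"].mean()
    fb = fpkm_b.groupby("gene_id")["fpkm"].mean()
    lfc = np.log2(fb + pseudocount) - np.log2(fa + pseudocount)
    lfc.name = "expression_log2fc"
    merged = classes.merge(lfc.reset_index(), on="gene_id", how="inner")

    groups: dict[str, np.ndarray] = {
        cls: grp["expression_log2fc"].to_numpy()
        for cls, grp in merged.groupby("class")
    }
    summaries = {
        cls: {
            "n": len(v),
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
        }
        for cls, v in groups.items()
    }
    tests: dict[tuple[str, str], dict] = {}
    names = sorted(groups)
    for i, ca in enumerate(names):
        for cb in names[i + 1:]:
            if len(groups[ca]) < 2 or len(groups[cb]) < 2:
                tests[(ca, cb)] = {"skipped": True, "p_value": float("nan")}
                continue
            t, p = stats.ttest_ind(groups[ca], groups[cb], equal_var=False)
            tests[(ca, cb)] = {"skipped": False, "t": float(t), "p_value": float(p)}
    return {"per_gene": merged, "summaries": summaries, "tests": tests}


def compare_fractions(
    iri_nuclear: pd.DataFrame,
    iri_cytoplasmic: pd.DataFrame,
    diff_records: Optional[pd.DataFrame] = None,
    min_reads: float = 3.0,
) -> dict:
    """Nuclear vs cytoplasmic retention-index comparison on shared introns.

    Returns paired summaries and t-tests for (a) introns restricted to
    differential calls when ``diff_records`` is given, and (b) introns
    detected as retained (>= ``min_reads`` supporting reads) in both
    fractions.
    """
    m = iri_nuclear.merge(
        iri_cytoplasmic, on="intron_id", suffixes=("_n", "_c"), how="inner"
    )
    if m.empty:
        raise ValueError("no shared introns between fractions")

    def _summarize(sub: pd.DataFrame) -> dict:
        nuc = sub["iri_n"].fillna(0.0).to_numpy()
        cyt = sub["iri_c"].fillna(0.0).to_numpy()
        if len(nuc) >= 2 and np.ptp(nuc - cyt) > 0:
            t, p = stats.ttest_rel(nuc, cyt)
        else:  # identical (or degenerate) fractions: no evidence of a shift
            t, p = float("nan"), 1.0
        return {
            "n": len(sub),
            "median_nuclear": float(np.median(nuc)) if len(nuc) else 0.0,
            "median_cytoplasmic": float(np.median(cyt)) if len(cyt) else 0.0,
            "t": float(t),
            "p_value": float(p),
        }

    out = {}
    if diff_records is not None:
        diff_ids = diff_records.loc[
            diff_records["direction"].isin(["up", "down"]), "intron_id"
        ]
        out["differential"] = _summarize(m[m["intron_id"].isin(diff_ids)])
    both = m[
        (m["supporting_reads_n"] >= min_reads) & (m["supporting_reads_c"] >= min_reads)
    ]
    out["retained_in_both"] = _summarize(both)
    out["all_shared"] = _summarize(m)
    return out


def call_deg(
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    min_fold: float = 2.0,
    min_fpkm: float = 1.0,
    alpha: float = 0.01,
    test=None,
) -> pd.DataFrame:
    """Simple differential-expression calls on replicate FPKM tables.

    Defaults: |log2FC| >= log2(min_fold), FPKM > min_fpkm in at least one
    condition, Welch t-test on log2(FPKM + 1) with p < alpha. ``test`` may
    replace the p-value function (signature ``test(xs, ys) -> p``).
    """
    if test is None:
        def test(xs, ys):
            if len(xs) < 2 or len(ys) < 2:
                return float("nan")
            return float(stats.ttest_ind(xs, ys, equal_var=False).pvalue)

    ga = fpkm_a.groupby("gene_id")["fpkm"].apply(list)
    gb = fpkm_b.groupby("gene_id")["fpkm"].apply(list)
    rows = []
    for gene_id in sorted(set(ga.index) & set(gb.index)):
        xa = np.asarray(ga[gene_id], dtype=float)
        xb = np.asarray(gb[gene_id], dtype=float)
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        lfc = float(np.log2(mean_b + 1e-9) - np.log2(mean_a + 1e-9))
        p = test(np.log2(xa + 1.0), np.log2(xb + 1.0))
        called = (
            abs(lfc) >= np.log2(min_fold)
            and max(mean_a, mean_b) > min_fpkm
            and (p == p and p < alpha)
        )
        rows.append(
            {
                "gene_id": gene_id,
                "fpkm_a": mean_a,
                "fpkm_b": mean_b,
                "log2fc": lfc,
                "p_value": p,
                "deg": bool(called),
            }
        )
    return pd.DataFrame(rows)
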