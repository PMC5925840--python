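"""Read counting over intron/exon units, FPKM, coverage and the retention index.

The retention index of an intron is its FPKM divided by the mean FPKM of its
two flanking exon units; an intron whose flanks are silent carries an
undefined index rather than a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .annotation_model import ExonUnit, GeneModel, IntronUnit

SupportRule = Literal["overlap", "contained", "min_overlap"]


@dataclass
class AlignmentRecord:
    """One uniquely mapped read/fragment; spliced reads carry >1 block."""

    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.blocks or sum(e - s for s, e in self.blocks) <= 0:
            raise ValueError("alignment must have positive total block length")
        self.blocks = sorted(self.blocks)


class _ChromIndex:
    """Block arrays for one chromosome, sorted by block start."""

    __slots__ = ("starts", "ends", "read_ids", "strands", "max_block")

    def __init__(self, starts, ends, read_ids, strands):
        order = np.argsort(starts, kind="stable")
        self.starts = np.asarray(starts)[order]
        self.ends = np.asarray(ends)[order]
        self.read_ids = np.asarray(read_ids)[order]
        self.strands = np.asarray(strands)[order]
        self.max_block = int((self.ends - self.starts).max()) if len(self.starts) else 0


@dataclass
class AlignmentSet:
    """Immutable, chromosome-indexed collection of aligned fragments."""

    sample_id: str = ""
    n_reads: int = 0
    _chroms: dict[str, _ChromIndex] = field(default_factory=dict, repr=False)

    @property
    def chroms(self) -> set[str]:
        return set(self._chroms)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[AlignmentRecord], sample_id: str = "") -> "AlignmentSet":
        buf: dict[str, list[list]] = {}
        n = 0
        for rec in records:
            b = buf.setdefault(rec.chrom, [[], [], [], []])
            strand = 1 if rec.strand == "+" else -1
            for s, e in rec.blocks:
                b[0].append(s)
                b[1].append(e)
                b[2].append(n)
                b[3].append(strand)
            n += 1
        return cls._assemble(buf, n, sample_id)

    @classmethod
    def from_arrays(
        cls,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        read_ids: Optional[np.ndarray] = None,
        strands: Optional[np.ndarray] = None,
        n_reads: Optional[int] = None,
        sample_id: str = "",
    ) -> "AlignmentSet":
        """Fast path for single-chromosome, single-block reads."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if read_ids is None:
            read_ids = np.arange(len(starts), dtype=np.int64)
        if strands is None:
            strands = np.ones(len(starts), dtype=np.int8)
        obj = cls(sample_id=sample_id, n_reads=int(n_reads if n_reads is not None else len(np.unique(read_ids))))
        obj._chroms[chrom] = _ChromIndex(starts, ends, read_ids, strands)
        return obj

    @classmethod
    def from_bed(cls, path: str, sample_id: str = "") -> "AlignmentSet":
        """Read BED12 (blocks encode splices) or BED6/BED3 alignments."""
        buf: dict[str, list[list]] = {}
        n = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
                chrom, start = f[0], int(f[1])
                strand = 1 if (len(f) < 6 or f[5] == "+") else -1
                if len(f) >= 12:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                    blocks = [(start + o, start + o + z) for o, z in zip(offsets, sizes)]
                else:
                    blocks = [(start, int(f[2]))]
                b = buf.setdefault(chrom, [[], [], [], []])
                for s, e in blocks:
                    b[0].append(s)
                    b[1].append(e)
                    b[2].append(n)
                    b[3].append(strand)
                n += 1
        return cls._assemble(buf, n, sample_id)

    @classmethod
    def from_sam(cls, path: str, sample_id: str = "", paired_as_fragments: bool = True) -> "AlignmentSet":
        """Read SAM/BAM via pysam; skips unmapped/secondary/supplementary.

        With ``paired_as_fragments`` both mates share one fragment id so a
        pair counts once.
        """
        import pysam

        buf: dict[str, list[list]] = {}
        frag_ids: dict[str, int] = {}
        n = 0
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if paired_as_fragments and aln.is_paired:
                    key = aln.query_name
                    if key in frag_ids:
                        rid = frag_ids.pop(key)
                    else:
                        rid = n
                        frag_ids[key] = rid
                        n += 1
                else:
                    rid = n
                    n += 1
                b = buf.setdefault(aln.reference_name, [[], [], [], []])
                strand = -1 if aln.is_reverse else 1
                for s, e in aln.get_blocks():
                    b[0].append(s)
                    b[1].append(e)
                    b[2].append(rid)
                    b[3].append(strand)
        return cls._assemble(buf, n, sample_id)

    @classmethod
    def _assemble(cls, buf: dict[str, list[list]], n_reads: int, sample_id: str) -> "AlignmentSet":
        obj = cls(sample_id=sample_id, n_reads=n_reads)
        for chrom, (starts, ends, rids, strands) in buf.items():
            obj._chroms[chrom] = _ChromIndex(
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
                np.asarray(rids, dtype=np.int64),
                np.asarray(strands, dtype=np.int8),
            )
        return obj

    # -- queries ------------------------------------------------------------

    def _candidates(self, chrom: str, start: int, end: int):
        idx = self._chroms.get(chrom)
        if idx is None or len(idx.starts) == 0:
            return None, slice(0, 0)
        lo = np.searchsorted(idx.starts, start - idx.max_block, side="left")
        hi = np.searchsorted(idx.starts, end, side="left")
        return idx, slice(lo, hi)

    def overlapping_blocks(self, chrom: str, start: int, end: int):
        """(starts, ends, read_ids) of blocks overlapping [start, end)."""
        idx, sl = self._candidates(chrom, start, end)
        if idx is None:
            z = np.empty(0, dtype=np.int64)
            return z, z, z
        s = idx.starts[sl]
        e = idx.ends[sl]
        r = idx.read_ids[sl]
        mask = e > start
        return s[mask], e[mask], r[mask]

    def coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base read-block coverage over [start, end)."""
        length = end - start
        cov = np.zeros(length + 1, dtype=np.float64)
        s, e, _ = self.overlapping_blocks(chrom, start, end)
        if len(s):
            np.add.at(cov, np.clip(s - start, 0, length), 1.0)
            np.add.at(cov, np.clip(e - start, 0, length), -1.0)
        return np.cumsum(cov)[:length]


# ---------------------------------------------------------------------------
# primitive measures
# ---------------------------------------------------------------------------


def count_feature_reads(
    alignments: AlignmentSet,
    chrom: str,
    start: int,
    end: int,
    rule: SupportRule = "overlap",
    min_overlap: int = 1,
) -> int:
    """Number of distinct fragments whose blocks touch ``[start, end)``.

    ``overlap``: >= 1 bp of block overlap (default; a spliced read whose gap
    spans the feature contributes nothing). ``contained``: every block inside
    the feature. ``min_overlap``: total block overlap >= ``min_overlap`` bp.
    """
    s, e, r = alignments.overlapping_blocks(chrom, start, end)
    if len(s) == 0:
        return 0
    if rule == "overlap":
        return int(len(np.unique(r)))
    ov = np.minimum(e, end) - np.maximum(s, start)
    if rule == "min_overlap":
        order = np.argsort(r, kind="stable")
        rs, os_ = r[order], ov[order]
        bounds = np.flatnonzero(np.r_[True, np.diff(rs) != 0])
        sums = np.add.reduceat(os_, bounds)
        return int(np.sum(sums >= min_overlap))
    if rule == "contained":
        # a read qualifies only if all of its blocks lie inside the feature;
        # blocks outside [start, end) never reach this function, so check
        # that the read's overlapping blocks are uncut and unique per read
        full = (s >= start) & (e <= end)
        good = np.unique(r[full])
        bad = np.unique(r[~full])
        return int(len(np.setdiff1d(good, bad, assume_unique=True)))
    raise ValueError(f"unknown support rule {rule!r}")


def fpkm(count: float, feature_length_bp: int, total_mapped_reads: int) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if feature_length_bp <= 0:
        raise ValueError("feature length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("library size must be positive")
    return count / (feature_length_bp / 1000.0) / (total_mapped_reads / 1e6)


def length_coverage(alignments: AlignmentSet, intron: IntronUnit) -> float:
    """Fraction of intron bases covered by at least one read block."""
    if intron.length <= 0:
        raise ValueError("intron length must be positive")
    s, e, _ = alignments.overlapping_blocks(intron.chrom, intron.start, intron.end)
    clipped = [(max(int(a), intron.start), min(int(b), intron.end)) for a, b in zip(s, e)]
    return iv.total_length(clipped) / intron.length


def compute_iri(intron_fpkm: float, flank_exon_fpkms: Sequence[float]) -> tuple[float, bool]:
    """Retention index and a defined-flag (False when flanks are silent)."""
    flank_mean = float(np.mean(flank_exon_fpkms))
    if flank_mean <= 0:
        return float("nan"), False
    return intron_fpkm / flank_mean, True


# ---------------------------------------------------------------------------
# per-sample quantification
# ---------------------------------------------------------------------------

IRI_COLUMNS = [
    "intron_id",
    "gene_id",
    "sample_id",
    "rel_position",
    "length",
    "supporting_reads",
    "intron_fpkm",
    "flank_left_fpkm",
    "flank_right_fpkm",
    "flank_mean_fpkm",
    "gene_fpkm",
    "length_coverage",
    "iri",
    "iri_defined",
    "flanks_expressed",
]


def quantify_sample(
    alignments: AlignmentSet,
    introns: Sequence[IntronUnit],
    exon_units: Sequence[ExonUnit],
    genes: Sequence[GeneModel],
    support_rule: SupportRule = "overlap",
    min_overlap: int = 1,
    min_flank_fpkm: float = 1.0,
    total_mapped_reads: Optional[int] = None,
) -> pd.DataFrame:
    """One IRIRecord row per intron for one sample.

    ``flanks_expressed`` marks introns whose two flanking exon units both
    exceed ``min_flank_fpkm`` (eligibility for retention calls).
    """
    lib = total_mapped_reads if total_mapped_reads is not None else alignments.n_reads
    if lib <= 0:
        raise ValueError("library size must be positive")
    unit_chroms = {u.chrom for u in introns} | {u.chrom for u in exon_units}
    missing = unit_chroms - alignments.chroms
    if unit_chroms and alignments.chroms and not (unit_chroms & alignments.chroms):
        raise ValueError(
            "no annotation chromosome found in alignments; missing: "
            + ", ".join(sorted(missing))
        )
    if missing:
        warnings.warn(
            "chromosomes without alignments: " + ", ".join(sorted(missing))
        )

    exon_fpkm: dict[str, float] = {}
    for eu in exon_units:
        c = count_feature_reads(alignments, eu.chrom, eu.start, eu.end, support_rule, min_overlap)
        exon_fpkm[eu.exon_id] = fpkm(c, eu.length, lib)

    gene_fpkm: dict[str, float] = {}
    for g in genes:
        merged = g.merged_exons()
        total = sum(
            count_feature_reads(alignments, g.chrom, s, e, support_rule, min_overlap)
            for s, e in merged
        )
        glen = iv.total_length(merged)
        gene_fpkm[g.gene_id] = fpkm(total, glen, lib) if glen else 0.0

    rows = []
    for u in introns:
        n = count_feature_reads(alignments, u.chrom, u.start, u.end, support_rule, min_overlap)
        ifpkm = fpkm(n, u.length, lib)
        fl = exon_fpkm.get(u.left_flank.exon_id) if u.left_flank else None
        fr = exon_fpkm.get(u.right_flank.exon_id) if u.right_flank else None
        flank_vals = [v for v in (fl, fr) if v is not None]
        if flank_vals:
            iri, defined = compute_iri(ifpkm, flank_vals)
        else:
            iri, defined = float("nan"), False
        rows.append(
            {
                "intron_id": u.intron_id,
                "gene_id": u.gene_id,
                "sample_id": alignments.sample_id,
                "rel_position": u.rel_position,
                "length": u.length,
                "supporting_reads": n,
                "intron_fpkm": ifpkm,
                "flank_left_fpkm": fl if fl is not None else float("nan"),
                "flank_right_fpkm": fr if fr is not None else float("nan"),
                "flank_mean_fpkm": float(np.mean(flank_vals)) if flank_vals else float("nan"),
                "gene_fpkm": gene_fpkm.get(u.gene_id, 0.0),
                "length_coverage": length_coverage(alignments, u),
                "iri": iri if defined else (0.0 if n == 0 else float("nan")),
                "iri_defined": defined,
                "flanks_expressed": bool(
                    fl is not None and fr is not None
                    and fl > min_flank_fpkm and fr > min_flank_fpkm
                ),
            }
        )
    return pd.DataFrame(rows, columns=IRI_COLUMNS)


def gene_fpkm_table(
    alignments: AlignmentSet,
    genes: Sequence[GeneModel],
    total_mapped_reads: Optional[int] = None,
) -> pd.DataFrame:
    """Per-gene FPKM over merged exons (one row per gene)."""
    lib = total_mapped_reads if total_mapped_reads is not None else alignments.n_reads
    rows = []
    for g in genes:
        merged = g.merged_exons()
        total = sum(
            count_feature_reads(alignments, g.chrom, s, e) for s, e in merged
        )
        glen = iv.total_length(merged)
        rows.append(
            {
                "gene_id": g.gene_id,
                "sample_id": alignments.sample_id,
                "fpkm": fpkm(total, glen, lib) if glen else 0.0,
            }
        )
    return pd.DataFrame(rows)
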