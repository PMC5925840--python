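"""ORF scanning, premature-termination-codon classification and NMD calls.

A stop codon counts as premature when it sits more than 50 spliced
nucleotides upstream of the last exon-exon junction; a PTC transcript
becomes an NMD candidate when its abundance rises more than twofold between
conditions with p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_model import AnnotationParseError, _parse_gff3_attributes, _parse_gtf_attributes

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class TranscriptModel:
    """A transcript's exon chain plus the annotated start codon.

    ``exons`` are genomic 0-based half-open intervals, sorted genomically;
    ``start_codon`` is a spliced-transcript offset (0-based, 5' to 3' in
    transcript orientation) pointing at the A of the ATG.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    start_codon: int

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        if self.start_codon < 0 or self.start_codon + 3 > self.spliced_length:
            raise ValueError(
                f"{self.transcript_id}: start codon outside spliced transcript"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        """Exon lengths in transcript (5' to 3') order."""
        lens = [e - s for s, e in self.exons]
        return lens if self.strand == "+" else lens[::-1]

    @property
    def junctions(self) -> list[int]:
        """Spliced positions of exon-exon junctions (after each non-last exon)."""
        out, cum = [], 0
        for ln in self.exon_lengths[:-1]:
            cum += ln
            out.append(cum)
        return out

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        seq = "".join(str(chrom_seq[s:e]) for s, e in self.exons)
        return seq.upper() if self.strand == "+" else reverse_complement(seq).upper()

    def genomic_to_spliced(self, pos: int) -> int:
        """Map a genomic base inside an exon to its spliced offset."""
        cum = 0
        for s, e in self.exons:
            if s <= pos < e:
                offset = cum + (pos - s)
                return offset if self.strand == "+" else self.spliced_length - 1 - offset
            cum += e - s
        raise ValueError(f"{self.transcript_id}: position {pos} not exonic")


@dataclass
class PTCCall:
    transcript_id: str
    stop_position: Optional[int]  # first base of the stop, spliced coords
    last_junction: Optional[int]
    distance: Optional[int]  # last_junction - stop end (spliced nt)
    is_ptc: bool
    no_stop: bool = False
    nmd_candidate: bool = False


def predict_orf(transcript: TranscriptModel, genome: Mapping[str, str]) -> Optional[int]:
    """Spliced position of the first in-frame stop at/after the start codon.

    Returns ``None`` when no in-frame stop exists. Raises when the annotated
    start is not ATG.
    """
    seq = transcript.spliced_sequence(genome)
    start = transcript.start_codon
    if seq[start:start + 3] != "ATG":
        raise ValueError(
            f"{transcript.transcript_id}: annotated start codon is "
            f"{seq[start:start + 3]!r}, not ATG"
        )
    for pos in range(start, len(seq) - 2, 3):
        if seq[pos:pos + 3] in STOP_CODONS:
            return pos
    return None


def classify_ptc(
    transcript: TranscriptModel,
    stop_position: Optional[int],
    min_distance: int = 50,
    measure_from: Literal["stop_end", "stop_start"] = "stop_end",
) -> PTCCall:
    """Apply the >50-nt upstream-of-last-junction rule.

    Distance defaults to ``last_junction - (stop + 3)``; single-exon
    transcripts have no junction and are never PTC.
    """
    junctions = transcript.junctions
    if stop_position is None:
        return PTCCall(transcript.transcript_id, None, junctions[-1] if junctions else None,
                       None, is_ptc=False, no_stop=True)
    if not junctions:
        return PTCCall(transcript.transcript_id, stop_position, None, None, is_ptc=False)
    last = junctions[-1]
    anchor = stop_position + 3 if measure_from == "stop_end" else stop_position
    distance = last - anchor
    return PTCCall(
        transcript.transcript_id, stop_position, last, distance,
        is_ptc=distance > min_distance,
    )


def call_nmd_targets(
    ptc_calls: Sequence[PTCCall],
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    test: Optional[Callable] = None,
    no_test: bool = False,
) -> pd.DataFrame:
    """Flag PTC transcripts whose abundance rose > ``min_fold`` (b vs a).

    Expression tables carry ``transcript_id``/``fpkm`` with one row per
    replicate. The default p-value is a Welch t-test on log2(FPKM + 1);
    fewer than two replicates leaves p undefined and requires ``no_test``.
    """
    if test is None:
        def test(xs, ys):
            if len(xs) < 2 or len(ys) < 2:
                return float("nan")
            return float(stats.ttest_ind(xs, ys, equal_var=False).pvalue)

    ga = fpkm_a.groupby("transcript_id")["fpkm"].apply(list)
    gb = fpkm_b.groupby("transcript_id")["fpkm"].apply(list)
    rows = []
    for call in ptc_calls:
        tid = call.transcript_id
        xa = np.asarray(ga.get(tid, []), dtype=float)
        xb = np.asarray(gb.get(tid, []), dtype=float)
        if len(xa) == 0 or len(xb) == 0:
            rows.append({"transcript_id": tid, "is_ptc": call.is_ptc, "fold": float("nan"),
                         "p_value": float("nan"), "nmd_candidate": False})
            continue
        fold = (xb.mean() + 1e-9) / (xa.mean() + 1e-9)
        p = test(np.log2(xa + 1.0), np.log2(xb + 1.0))
        if p != p and not no_test and (len(xa) < 2 or len(xb) < 2):
            raise ValueError(
                f"{tid}: <2 replicates; pass no_test=True to call without a p-value"
            )
        significant = no_test or (p == p and p < alpha)
        candidate = bool(call.is_ptc and fold > min_fold and significant)
        call.nmd_candidate = candidate
        rows.append({"transcript_id": tid, "is_ptc": call.is_ptc, "fold": float(fold),
                     "p_value": float(p), "nmd_candidate": candidate})
    return pd.DataFrame(rows)


def intron_features(
    introns: Sequence,
    genome: Mapping[str, str],
) -> pd.DataFrame:
    """Per-intron length and GC fraction (intron objects need chrom/start/end)."""
    rows = []
    for u in introns:
        chrom_seq = genome[u.chrom]
        if u.end > len(chrom_seq) or u.start < 0:
            raise ValueError(f"{u.intron_id}: interval outside chromosome")
        seq = str(chrom_seq[u.start:u.end])
        rows.append(
            {
                "intron_id": u.intron_id,
                "gene_id": u.gene_id,
                "length": u.end - u.start,
                "gc": gc_fraction(seq),
            }
        )
    return pd.DataFrame(rows)


def compare_intron_groups(
    features: pd.DataFrame, group_ids: Mapping[str, Sequence[str]], column: str
) -> dict:
    """Welch t-test of a feature column between named intron-id groups."""
    values = {
        label: features.loc[features["intron_id"].isin(ids), column].to_numpy()
        for label, ids in group_ids.items()
    }
    labels = sorted(values)
    tests = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            if len(values[la]) < 2 or len(values[lb]) < 2:
                tests[(la, lb)] = float("nan")
            else:
                tests[(la, lb)] = float(
                    stats.ttest_ind(values[la], values[lb], equal_var=False).pvalue
                )
    return {
        "medians": {k: float(np.median(v)) if len(v) else float("nan") for k, v in values.items()},
        "p_values": tests,
    }


def load_transcripts_from_gtf(path: str) -> list[TranscriptModel]:
    """Build transcript models from GTF/GFF3 exon + start_codon features."""
    exons: dict[str, dict] = {}
    starts: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise AnnotationParseError(f"{path}:{lineno}: expected 9 fields")
            chrom, _s, ftype, start_s, end_s, _sc, strand, _fr, attr_s = f
            if ftype not in ("exon", "start_codon"):
                continue
            gff3 = "=" in attr_s and '"' not in attr_s.split(";")[0]
            attrs = _parse_gff3_attributes(attr_s) if gff3 else _parse_gtf_attributes(attr_s)
            tid = attrs.get("transcript_id") or attrs.get("Parent")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                raise AnnotationParseError(f"{path}:{lineno}: missing transcript id")
            start, end = int(start_s) - 1, int(end_s)
            if ftype == "exon":
                rec = exons.setdefault(
                    tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exons": []}
                )
                rec["exons"].append((start, end))
            else:
                starts[tid] = (start, end)

    out = []
    for tid, rec in exons.items():
        if tid not in starts:
            continue
        s, e = starts[tid]
        genomic_first = s if rec["strand"] == "+" else e - 1
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            start_codon=0,
        )
        tm.start_codon = tm.genomic_to_spliced(genomic_first)
        out.append(tm)
    return out
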