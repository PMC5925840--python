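"""Gene models and non-overlapping intron/exon unit construction.

Annotated introns frequently overlap exons of other isoforms or genes, which
confounds retention estimates. This module rebuilds per-gene unit sets so
that every intron unit shares no base with any exon of the configured exon
universe, and every exon unit shares no base with any annotated intron.

Internal coordinates are 0-based half-open throughout; GTF/GFF3 readers
convert at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from . import _intervals as iv

log = logging.getLogger(__name__)

Strand = Literal["+", "-"]


class AnnotationParseError(ValueError):
    """Raised for malformed annotation lines; carries the line number."""


@dataclass
class GeneModel:
    """A gene's span, strand and transcript exon chains."""

    gene_id: str
    chrom: str
    strand: Strand
    span_start: int
    span_end: int
    #: transcript_id -> sorted list of (start, end) exon intervals
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.span_start >= self.span_end:
            raise ValueError(
                f"gene {self.gene_id}: span_start must be < span_end "
                f"({self.span_start} >= {self.span_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site (span_end side on the minus strand)."""
        return self.span_start if self.strand == "+" else self.span_end

    @property
    def tts(self) -> int:
        return self.span_end if self.strand == "+" else self.span_start

    @property
    def length(self) -> int:
        return self.span_end - self.span_start

    def merged_exons(self) -> list[tuple[int, int]]:
        return iv.merge([e for chain in self.transcripts.values() for e in chain])

    def annotated_introns(self) -> list[tuple[int, int]]:
        """Union over transcripts of gaps between consecutive exons."""
        out: list[tuple[int, int]] = []
        for chain in self.transcripts.values():
            out.extend(iv.gaps(chain))
        return iv.merge(out)


@dataclass(frozen=True)
class ExonUnit:
    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Strand

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntronUnit:
    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: Strand
    left_flank: Optional[ExonUnit]
    right_flank: Optional[ExonUnit]
    rel_position: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def flanks(self) -> tuple[Optional[ExonUnit], Optional[ExonUnit]]:
        return self.left_flank, self.right_flank


# ---------------------------------------------------------------------------
# annotation parsing
# ---------------------------------------------------------------------------


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            key, value = chunk.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def parse_annotation(path: str) -> list[GeneModel]:
    """Parse a GTF or GFF3 file into :class:`GeneModel` objects.

    Only ``exon`` features are used. GTF attributes must carry
    ``gene_id``/``transcript_id``; GFF3 exons must carry ``Parent`` pointing
    at a transcript feature whose own ``Parent`` (or, failing that, its
    ``ID``) identifies the gene. 1-based inclusive coordinates are converted
    to 0-based half-open.
    """
    # transcript_id -> (gene_id, chrom, strand, [exons])
    tx: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    tx_parent: dict[str, str] = {}  # GFF3 transcript -> gene
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            gff3 = "=" in attr_s and '"' not in attr_s.split(";")[0]
            attrs = _parse_gff3_attributes(attr_s) if gff3 else _parse_gtf_attributes(attr_s)
            if ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID") or attrs.get("transcript_id")
                gid = attrs.get("Parent") or attrs.get("gene_id")
                if tid and gid:
                    tx_parent[tid] = gid
                continue
            if ftype != "exon":
                continue
            try:
                start = int(start_s) - 1  # GTF/GFF3 are 1-based inclusive
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if start < 0 or end <= start:
                raise AnnotationParseError(
                    f"{path}:{lineno}: invalid interval [{start_s}, {end_s}]"
                )
            if strand not in ("+", "-"):
                raise AnnotationParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            if gff3:
                tid = attrs.get("Parent") or attrs.get("transcript_id")
                gid = attrs.get("gene_id")  # resolved from tx_parent later if absent
            else:
                tid = attrs.get("transcript_id")
                gid = attrs.get("gene_id")
            if tid is None:
                raise AnnotationParseError(
                    f"{path}:{lineno}: exon without transcript identifier"
                )
            if tid not in tx:
                tx[tid] = (gid or "", chrom, strand, [])
            tx[tid][3].append((start, end))

    genes: dict[str, GeneModel] = {}
    for tid, (gid, chrom, strand, exons) in tx.items():
        if not exons:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        gid = gid or tx_parent.get(tid, tid)
        exons = sorted(exons)
        gene = genes.get(gid)
        if gene is None:
            genes[gid] = GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,  # type: ignore[arg-type]
                span_start=exons[0][0],
                span_end=exons[-1][1],
                transcripts={tid: exons},
            )
        else:
            gene.transcripts[tid] = exons
            gene.span_start = min(gene.span_start, exons[0][0])
            gene.span_end = max(gene.span_end, exons[-1][1])
    return list(genes.values())


# ---------------------------------------------------------------------------
# unit construction
# ---------------------------------------------------------------------------


def relative_position(
    interval: tuple[int, int],
    gene: GeneModel,
    mode: Literal["midpoint", "five_prime"] = "midpoint",
) -> float:
    """Gene-body position in [0, 1] from TSS, strand-aware."""
    if gene.length == 0:
        raise ValueError(f"gene {gene.gene_id} has zero-length span")
    if mode == "midpoint":
        anchor = (interval[0] + interval[1]) / 2
    elif mode == "five_prime":
        anchor = interval[0] if gene.strand == "+" else interval[1]
    else:
        raise ValueError(f"unknown position mode {mode!r}")
    rel = (anchor - gene.span_start) / gene.length
    if gene.strand == "-":
        rel = 1.0 - rel
    return min(max(rel, 0.0), 1.0)


def build_units(
    genes: Iterable[GeneModel],
    exon_universe: Literal["same_gene", "all_genes"] = "all_genes",
    min_fragment: int = 10,
    position_mode: Literal["midpoint", "five_prime"] = "midpoint",
) -> tuple[list[IntronUnit], list[ExonUnit]]:
    """Build exon-free intron units and intron-free exon units.

    Per gene: introns are gaps between consecutive exons of each transcript,
    merged across transcripts; bases overlapping any exon of the universe are
    subtracted; surviving fragments shorter than ``min_fragment`` bp are
    dropped. Exon units are the gene's merged exons minus any annotated
    intron of the universe. Each intron unit records its genomically nearest
    flanking exon units of the same gene.
    """
    genes = list(genes)
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    intron_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if exon_universe == "all_genes":
        for g in genes:
            exon_by_chrom.setdefault(g.chrom, []).extend(g.merged_exons())
            intron_by_chrom.setdefault(g.chrom, []).extend(g.annotated_introns())
        exon_by_chrom = {c: iv.merge(v) for c, v in exon_by_chrom.items()}
        intron_by_chrom = {c: iv.merge(v) for c, v in intron_by_chrom.items()}
    elif exon_universe != "same_gene":
        raise ValueError(f"unknown exon_universe {exon_universe!r}")

    intron_units: list[IntronUnit] = []
    exon_units: list[ExonUnit] = []
    for gene in genes:
        own_exons = gene.merged_exons()
        own_introns = gene.annotated_introns()
        if exon_universe == "all_genes":
            exon_uni = exon_by_chrom.get(gene.chrom, [])
            intron_uni = intron_by_chrom.get(gene.chrom, [])
        else:
            exon_uni = own_exons
            intron_uni = own_introns

        gene_exon_units = []
        for i, (s, e) in enumerate(iv.subtract(own_exons, intron_uni)):
            if e - s < min_fragment:
                continue
            gene_exon_units.append(
                ExonUnit(f"{gene.gene_id}:e{i}", gene.gene_id, gene.chrom, s, e, gene.strand)
            )
        exon_units.extend(gene_exon_units)

        frags = [
            (s, e)
            for s, e in iv.subtract(own_introns, exon_uni)
            if e - s >= min_fragment
        ]
        for i, (s, e) in enumerate(frags):
            left = None
            for eu in gene_exon_units:
                if eu.end <= s and (left is None or eu.end > left.end):
                    left = eu
            right = None
            for eu in gene_exon_units:
                if eu.start >= e and (right is None or eu.start < right.start):
                    right = eu
            intron_units.append(
                IntronUnit(
                    intron_id=f"{gene.gene_id}:i{i}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    start=s,
                    end=e,
                    strand=gene.strand,
                    left_flank=left,
                    right_flank=right,
                    rel_position=relative_position((s, e), gene, position_mode),
                )
            )
    return intron_units, exon_units


def write_units_bed(
    intron_units: Iterable[IntronUnit],
    exon_units: Iterable[ExonUnit],
    intron_path: str,
    exon_path: str,
) -> None:
    """Write unit sets as BED6 (intron score = rel_position x 1000)."""
    with open(intron_path, "w") as fh:
        for u in intron_units:
            fh.write(
                f"{u.chrom}\t{u.start}\t{u.end}\t{u.intron_id}\t"
                f"{round(u.rel_position * 1000)}\t{u.strand}\n"
            )
    with open(exon_path, "w") as fh:
        for u in exon_units:
            fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{u.exon_id}\t0\t{u.strand}\n")
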