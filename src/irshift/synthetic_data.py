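"""Seeded simulator for annotation, RNA-seq and ChIP-seq test data.

Every pipeline stage can be exercised without external data: the simulator
emits gene models (GTF/FASTA), spliced RNA-seq fragments with per-intron
retention levels and a programmable 5'/3' bias in retention changes, and
ChIP-seq fragments with flat, globally reduced or promoter-shifted gene-body
profiles plus uniform input controls. A truth table records every planted
quantity.

RNA-seq fragments are drawn molecule-wise: each fragment first samples which
introns its source molecule retains (length-weighted, so coverage is uniform
per base), then a uniform position along that molecule; fragments spanning a
splice junction of a removed intron become multi-block alignments.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import _intervals as iv
from .annotation_model import GeneModel, IntronUnit, build_units
from .nmd_features import STOP_CODONS, TranscriptModel, reverse_complement
from .quantification import AlignmentRecord, AlignmentSet

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
]


@dataclass(frozen=True)
class SimulationScenario:
    """Parameter block for one simulated dataset (fully seeded)."""

    seed: int = 0
    n_genes: int = 50
    chrom: str = "chrSim"
    min_exons: int = 3
    max_exons: int = 6
    exon_len: tuple[int, int] = (250, 550)
    intron_len: tuple[int, int] = (200, 450)
    intergenic: tuple[int, int] = (6000, 9000)
    # RNA-seq
    read_length: int = 100
    depth: float = 20.0  # expected exonic read coverage at expression 1
    expression: tuple[float, float] = (0.6, 1.6)
    base_retention: tuple[float, float] = (0.1, 0.3)
    retention_up: tuple[float, float] = (0.08, 0.45)  # (cond a, cond b)
    retention_down: tuple[float, float] = (0.45, 0.08)
    frac_up: float = 0.18
    frac_down: float = 0.18
    up_beta: tuple[float, float] = (2.0, 5.0)  # 5'-biased positions
    down_beta: tuple[float, float] = (5.0, 2.0)  # 3'-biased positions
    rna_noise_sd: float = 0.08  # per (gene, replicate) gamma multiplier
    intron_noise_sd: float = 0.05  # per (intron, replicate) gamma on r
    expression_shift_down_genes: float = 0.0  # log2 shift planted on down-only genes
    # ChIP-seq
    chip_read_length: int = 50
    chip_body_density: float = 6.0  # expected read starts per body bp at level 1
    chip_background: float = 0.15  # background density as a fraction of body density
    chip_gene_noise_sd: float = 0.05
    chip_global_scale_mut: float = 0.45  # genic level of unshifted mutant genes
    shift_front: float = 2.0  # front-half level multiplier of shifted genes
    shift_rear: float = 0.3
    frac_me2_only: float = 0.2
    frac_me3_only: float = 0.2
    frac_both: float = 0.2
    input_depth_factor: float = 1.0
    # ORF planting
    plant_orfs: bool = True
    ptc_fraction: float = 0.4

    def with_(self, **kw) -> "SimulationScenario":
        return replace(self, **kw)


def paper_scenario(seed: int = 0, n_genes: int = 150) -> SimulationScenario:
    """Preset emulating the study's qualitative structure: 5'-biased IRI
    gains plus 3'-biased losses coupled to me2/me3 promoter-proximal shifts
    on planted gene subsets."""
    return SimulationScenario(seed=seed, n_genes=n_genes)


# ---------------------------------------------------------------------------


@dataclass
class _GeneStruct:
    gene: GeneModel
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]  # genomic order
    expression: float
    transcript: Optional[TranscriptModel] = None


class Simulator:
    """Deterministic dataset generator for one scenario.

    Randomness is partitioned per artefact: identical (seed, library)
    requests reproduce byte-identical output regardless of call order.
    """

    def __init__(self, scenario: SimulationScenario):
        self.scenario = scenario
        self._build_annotation()
        self._plan_truth()

    # -- annotation ---------------------------------------------------------

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng([self.scenario.seed, *key])

    def _build_annotation(self) -> None:
        sc = self.scenario
        rng = self._rng(0)
        structs: list[_GeneStruct] = []
        pos = int(rng.integers(*sc.intergenic))
        for i in range(sc.n_genes):
            n_ex = int(rng.integers(sc.min_exons, sc.max_exons + 1))
            exon_lens = rng.integers(sc.exon_len[0], sc.exon_len[1] + 1, n_ex)
            intron_lens = rng.integers(sc.intron_len[0], sc.intron_len[1] + 1, n_ex - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            exons, introns = [], []
            cur = pos
            for j in range(n_ex):
                exons.append((cur, cur + int(exon_lens[j])))
                cur += int(exon_lens[j])
                if j < n_ex - 1:
                    introns.append((cur, cur + int(intron_lens[j])))
                    cur += int(intron_lens[j])
            gid = f"gene{i:04d}"
            gene = GeneModel(gid, sc.chrom, strand, pos, cur, {f"{gid}.t1": exons})
            expr = float(rng.uniform(*sc.expression))
            structs.append(_GeneStruct(gene, exons, introns, expr))
            pos = cur + int(rng.integers(*sc.intergenic))
        self.genome_length = pos + int(rng.integers(*sc.intergenic))
        self.structs = structs
        self.genes = [s.gene for s in structs]
        self._by_gid = {s.gene.gene_id: s for s in structs}
        self.intron_units, self.exon_units = build_units(self.genes)

        seq = rng.choice(_BASES, size=self.genome_length)
        if sc.plant_orfs:
            self._plant_orfs(rng, seq)
        self.genome = {sc.chrom: "".join(seq)}

    def _plant_orfs(self, rng: np.random.Generator, seq: np.ndarray) -> None:
        sc = self.scenario
        self._ptc_truth: dict[str, bool] = {}
        for s in self.structs:
            tm = TranscriptModel(
                transcript_id=next(iter(s.gene.transcripts)),
                gene_id=s.gene.gene_id,
                chrom=s.gene.chrom,
                strand=s.gene.strand,
                exons=s.exons,
                start_codon=30,
            )
            s.transcript = tm
            junctions = tm.junctions
            splen = tm.spliced_length
            is_ptc = bool(junctions) and rng.random() < sc.ptc_fraction
            if is_ptc and junctions:
                # stop must end >50 nt before the last junction
                limit = junctions[-1] - 60
                n_codons = max(2, (limit - tm.start_codon - 3) // 3)
                n_codons = int(rng.integers(2, n_codons + 1))
            else:
                # stop inside the last exon (or past the 50 nt mark)
                lo = (junctions[-1] if junctions else tm.start_codon + 6) + 12
                hi = splen - 6
                target = int(min(max(lo, tm.start_codon + 6), hi))
                n_codons = max(1, (target - tm.start_codon - 3) // 3)
            stop_pos = tm.start_codon + 3 + 3 * n_codons
            body = "".join(
                _NON_STOP_CODONS[k]
                for k in rng.choice(len(_NON_STOP_CODONS), size=n_codons)
            )
            stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
            spliced = list("".join(rng.choice(_BASES, size=splen)))
            spliced[tm.start_codon:stop_pos + 3] = list("ATG" + body + stop)
            spliced = "".join(spliced)
            genomic = spliced if s.gene.strand == "+" else reverse_complement(spliced)
            cur = 0
            for (a, b) in s.exons:
                seq[a:b] = list(genomic[cur:cur + (b - a)])
                cur += b - a
            self._ptc_truth[tm.transcript_id] = is_ptc

    # -- truth planning -----------------------------------------------------

    def _plan_truth(self) -> None:
        sc = self.scenario
        rng = self._rng(1)
        units = sorted(self.intron_units, key=lambda u: u.intron_id)
        n = len(units)
        r_a = rng.uniform(*sc.base_retention, size=n)
        r_b = r_a.copy()
        direction = np.array(["unchanged"] * n, dtype=object)

        n_up = int(round(sc.frac_up * n))
        n_down = int(round(sc.frac_down * n))
        pos = np.array([u.rel_position for u in units])
        available = np.ones(n, dtype=bool)

        def _pick(n_pick: int, beta: tuple[float, float]) -> list[int]:
            chosen = []
            for target in rng.beta(*beta, size=n_pick):
                idx = np.flatnonzero(available)
                if len(idx) == 0:
                    break
                best = idx[np.argmin(np.abs(pos[idx] - target))]
                available[best] = False
                chosen.append(int(best))
            return chosen

        up_idx = _pick(n_up, sc.up_beta)
        down_idx = _pick(n_down, sc.down_beta)
        for i in up_idx:
            r_a[i], r_b[i] = sc.retention_up
            direction[i] = "up"
        for i in down_idx:
            r_a[i], r_b[i] = sc.retention_down
            direction[i] = "down"

        self.truth_introns = pd.DataFrame(
            {
                "intron_id": [u.intron_id for u in units],
                "gene_id": [u.gene_id for u in units],
                "rel_position": pos,
                "r_a": r_a,
                "r_b": r_b,
                "direction": direction,
            }
        )
        self._r_by_intron = {
            row.intron_id: (row.r_a, row.r_b)
            for row in self.truth_introns.itertuples()
        }

        # ChIP shift classes: deterministic assignment by shuffled order
        gids = [g.gene_id for g in self.genes]
        order = rng.permutation(len(gids))
        n1 = int(round(sc.frac_me2_only * len(gids)))
        n2 = int(round(sc.frac_me3_only * len(gids)))
        n3 = int(round(sc.frac_both * len(gids)))
        me2 = np.zeros(len(gids), dtype=bool)
        me3 = np.zeros(len(gids), dtype=bool)
        me2[order[:n1]] = True
        me3[order[n1:n1 + n2]] = True
        me2[order[n1 + n2:n1 + n2 + n3]] = True
        me3[order[n1 + n2:n1 + n2 + n3]] = True
        types = np.where(me2 & me3, "III", np.where(me2, "I", np.where(me3, "II", "IV")))
        self.truth_genes = pd.DataFrame(
            {
                "gene_id": gids,
                "expression": [s.expression for s in self.structs],
                "me2_shifted": me2,
                "me3_shifted": me3,
                "shift_type": types,
            }
        )
        self._shift_by_gid = {
            row.gene_id: {"me2": row.me2_shifted, "me3": row.me3_shifted}
            for row in self.truth_genes.itertuples()
        }
        self.truth_transcripts = pd.DataFrame(
            {
                "transcript_id": list(getattr(self, "_ptc_truth", {})),
                "is_ptc": list(getattr(self, "_ptc_truth", {}).values()),
            }
        )

    # -- RNA-seq ------------------------------------------------------------

    def rnaseq(
        self,
        condition: Literal["a", "b"],
        replicate: int = 1,
        return_records: bool = False,
    ):
        """Simulate one strand-specific RNA-seq library.

        Returns an :class:`AlignmentSet` (and the raw records when
        ``return_records`` is set, for file export).
        """
        sc = self.scenario
        cond_idx = {"a": 0, "b": 1}[condition]
        rng = self._rng(2, cond_idx, replicate)
        L = sc.read_length
        records: list[AlignmentRecord] = []
        rcol = "r_a" if condition == "a" else "r_b"
        truth = self.truth_introns.set_index("intron_id")[rcol]

        for s in self.structs:
            gid = s.gene.gene_id
            k = len(s.introns)
            r = np.array(
                [truth.get(f"{gid}:i{j}", 0.0) for j in range(k)], dtype=float
            )
            if sc.intron_noise_sd > 0 and k:
                shape = 1.0 / sc.intron_noise_sd**2
                r = np.clip(r * rng.gamma(shape, 1.0 / shape, size=k), 0.0, 1.0)
            gmult = 1.0
            if sc.rna_noise_sd > 0:
                shape = 1.0 / sc.rna_noise_sd**2
                gmult = float(rng.gamma(shape, 1.0 / shape))
            cov = sc.depth * s.expression * gmult
            if sc.expression_shift_down_genes:
                # optional planted expression change, applied in condition b
                if condition == "b" and self._gene_shift_factor(gid) != 1.0:
                    cov *= self._gene_shift_factor(gid)
            exon_lens = np.array([b - a for a, b in s.exons])
            intron_lens = np.array([b - a for a, b in s.introns])
            splen = int(exon_lens.sum())

            # enumerate retention patterns, weight by molecule length so that
            # per-base coverage is uniform along each molecule
            patterns = list(itertools.product((0, 1), repeat=k)) if k else [()]
            pat = np.array(patterns, dtype=float)
            probs = np.prod(np.where(pat == 1, r, 1 - r), axis=1) if k else np.ones(1)
            mlens = splen + (pat @ intron_lens if k else np.zeros(1))
            weights = probs * (mlens + L - 1)
            lam = cov / L * float(np.sum(weights))
            n_frag = rng.poisson(lam)
            if n_frag == 0:
                continue
            choice = rng.choice(len(patterns), size=n_frag, p=weights / weights.sum())

            for pi in np.unique(choice):
                pattern = patterns[int(pi)]
                m = int(mlens[pi])
                blocks = self._molecule_blocks(s, pattern)
                cum = np.concatenate([[0], np.cumsum([b - a for a, b in blocks])])
                n_p = int(np.sum(choice == pi))
                starts = rng.integers(-(L - 1), m, size=n_p)
                for s0 in starts:
                    a = max(int(s0), 0)
                    b = min(int(s0) + L, m)
                    if b <= a:
                        continue
                    records.append(
                        AlignmentRecord(
                            chrom=sc.chrom,
                            strand=s.gene.strand,
                            blocks=self._map_span(blocks, cum, a, b),
                        )
                    )
        sample_id = f"rna_{condition}_rep{replicate}"
        aset = AlignmentSet.from_records(records, sample_id=sample_id)
        if return_records:
            return aset, records
        return aset

    def _gene_shift_factor(self, gid: str) -> float:
        sc = self.scenario
        if not sc.expression_shift_down_genes:
            return 1.0
        sub = self.truth_introns[self.truth_introns["gene_id"] == gid]
        if (sub["direction"] == "down").any() and not (sub["direction"] == "up").any():
            return 2.0 ** sc.expression_shift_down_genes
        return 1.0

    @staticmethod
    def _molecule_blocks(s: _GeneStruct, pattern: Sequence[int]) -> list[tuple[int, int]]:
        parts = []
        for j, ex in enumerate(s.exons):
            parts.append(ex)
            if j < len(s.introns) and pattern[j]:
                parts.append(s.introns[j])
        return iv.merge(parts)

    @staticmethod
    def _map_span(
        blocks: list[tuple[int, int]], cum: np.ndarray, a: int, b: int
    ) -> list[tuple[int, int]]:
        """Map molecule-coordinate span [a, b) onto genomic blocks."""
        out = []
        i = int(np.searchsorted(cum, a, side="right")) - 1
        while i < len(blocks) and cum[i] < b:
            bs, be = blocks[i]
            lo = bs + max(a - int(cum[i]), 0)
            hi = bs + min(b - int(cum[i]), be - bs)
            if hi > lo:
                out.append((lo, hi))
            i += 1
        return out

    # -- ChIP-seq -----------------------------------------------------------

    def chip(
        self,
        mark: Literal["me1", "me2", "me3"],
        condition: Literal["wt", "mut"],
        shape: Optional[str] = None,
    ) -> AlignmentSet:
        """Simulate one ChIP library (50-bp single-end, one block per read).

        WT genes carry a flat unit-level body profile. Mutant genes are
        globally reduced, and genes planted as shifted for ``mark`` gain
        signal over the front half of the body and lose it over the rear
        half (TSS-oriented). ``shape`` overrides the per-gene truth with one
        of flat / reduced / shifted for every gene.
        """
        sc = self.scenario
        mark_idx = {"me1": 0, "me2": 1, "me3": 2}[mark]
        cond_idx = {"wt": 0, "mut": 1}[condition]
        rng = self._rng(3, mark_idx, cond_idx)
        starts_all = []

        for s in self.structs:
            g = s.gene
            if shape is not None:
                shifted = shape == "shifted"
                scale = 1.0 if shape == "flat" else sc.chip_global_scale_mut
            elif condition == "wt":
                shifted, scale = False, 1.0
            else:
                shifted = bool(self._shift_by_gid[g.gene_id].get(mark, False))
                scale = sc.chip_global_scale_mut
            front = scale * (sc.shift_front if shifted else 1.0)
            rear = scale * (sc.shift_rear if shifted else 1.0)
            gmult = 1.0
            if sc.chip_gene_noise_sd > 0:
                shp = 1.0 / sc.chip_gene_noise_sd**2
                gmult = float(rng.gamma(shp, 1.0 / shp))
            mid = (g.span_start + g.span_end) // 2
            if g.strand == "+":
                halves = [(g.span_start, mid, front), (mid, g.span_end, rear)]
            else:  # front half sits at the TSS, genomically right
                halves = [(g.span_start, mid, rear), (mid, g.span_end, front)]
            for a, b, level in halves:
                lam = level * gmult * sc.chip_body_density * (b - a)
                n = rng.poisson(lam)
                if n:
                    starts_all.append(rng.integers(a, b, size=n))

        n_bg = rng.poisson(sc.chip_background * sc.chip_body_density * self.genome_length)
        if n_bg:
            starts_all.append(rng.integers(0, self.genome_length - sc.chip_read_length, size=n_bg))
        starts = (
            np.concatenate(starts_all) if starts_all else np.empty(0, dtype=np.int64)
        )
        return AlignmentSet.from_arrays(
            sc.chrom,
            starts,
            starts + sc.chip_read_length,
            n_reads=len(starts),
            sample_id=f"chip_{mark}_{condition}",
        )

    def chip_input(self, condition: Literal["wt", "mut"] = "wt") -> AlignmentSet:
        """Uniform input-control library at depth matched to a ChIP library."""
        sc = self.scenario
        rng = self._rng(4, {"wt": 0, "mut": 1}[condition])
        body_bp = sum(g.length for g in self.genes)
        total = sc.input_depth_factor * sc.chip_body_density * (
            body_bp + sc.chip_background * self.genome_length
        )
        n = rng.poisson(total)
        starts = rng.integers(0, self.genome_length - sc.chip_read_length, size=n)
        return AlignmentSet.from_arrays(
            sc.chrom,
            starts,
            starts + sc.chip_read_length,
            n_reads=n,
            sample_id=f"input_{condition}",
        )

    # -- export -------------------------------------------------------------

    def write_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            for s in self.structs:
                g = s.gene
                for tid, exons in g.transcripts.items():
                    for a, b in exons:
                        fh.write(
                            f"{g.chrom}\tirshift_sim\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                            f'gene_id "{g.gene_id}"; transcript_id "{tid}";\n'
                        )
                if s.transcript is not None:
                    tm = s.transcript
                    first = tm.start_codon
                    # start codon genomic span (may straddle a junction; here
                    # planted well inside the first exon, so contiguous)
                    gpos = sorted(
                        self._spliced_to_genomic(tm, first + o) for o in range(3)
                    )
                    fh.write(
                        f"{g.chrom}\tirshift_sim\tstart_codon\t{gpos[0] + 1}\t{gpos[-1] + 1}\t.\t"
                        f'{g.strand}\t0\tgene_id "{g.gene_id}"; transcript_id "{tm.transcript_id}";\n'
                    )

    @staticmethod
    def _spliced_to_genomic(tm: TranscriptModel, pos: int) -> int:
        if tm.strand == "-":
            pos = tm.spliced_length - 1 - pos
        cum = 0
        for a, b in tm.exons:
            if pos < cum + (b - a):
                return a + (pos - cum)
            cum += b - a
        raise ValueError("spliced position outside transcript")

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_truth(self, prefix: str) -> None:
        self.truth_introns.to_csv(f"{prefix}.introns.tsv", sep="\t", index=False)
        self.truth_genes.to_csv(f"{prefix}.genes.tsv", sep="\t", index=False)
        self.truth_transcripts.to_csv(f"{prefix}.transcripts.tsv", sep="\t", index=False)


def write_bed12(records: Sequence[AlignmentRecord], path: str, sorted_output: bool = True) -> None:
    """Write alignment records (blocks encode splices) as BED12."""
    recs = sorted(records, key=lambda r: (r.chrom, r.blocks[0][0])) if sorted_output else records
    with open(path, "w") as fh:
        for i, r in enumerate(recs):
            start = r.blocks[0][0]
            end = r.blocks[-1][1]
            sizes = ",".join(str(b - a) for a, b in r.blocks)
            offsets = ",".join(str(a - start) for a, b in r.blocks)
            fh.write(
                f"{r.chrom}\t{start}\t{end}\tread{i}\t0\t{r.strand}\t{start}\t{end}\t0\t"
                f"{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )


def write_sam(
    records: Sequence[AlignmentRecord], path: str, chrom_lengths: dict[str, int]
) -> None:
    """Write single-end alignment records as headerful SAM (N for splices)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        recs = sorted(records, key=lambda r: (r.chrom, r.blocks[0][0]))
        for i, r in enumerate(recs):
            cigar = ""
            for j, (a, b) in enumerate(r.blocks):
                if j:
                    cigar += f"{a - r.blocks[j - 1][1]}N"
                cigar += f"{b - a}M"
            flag = 16 if r.strand == "-" else 0
            seqlen = sum(b - a for a, b in r.blocks)
            fh.write(
                f"read{i}\t{flag}\t{r.chrom}\t{r.blocks[0][0] + 1}\t60\t{cigar}\t*\t0\t0\t"
                f"{'A' * seqlen}\t*\n"
            )


# -- spec-level convenience wrappers ---------------------------------------


def generate_annotation(
    scenario: SimulationScenario, gtf_path: Optional[str] = None, fasta_path: Optional[str] = None
) -> Simulator:
    """Build the simulated annotation/genome; optionally write GTF + FASTA."""
    sim = Simulator(scenario)
    if gtf_path:
        sim.write_gtf(gtf_path)
    if fasta_path:
        sim.write_fasta(fasta_path)
    return sim


def simulate_rnaseq(
    sim: Simulator, condition: Literal["a", "b"], replicate: int = 1
) -> tuple[AlignmentSet, pd.DataFrame]:
    """One RNA-seq library plus the intron truth table."""
    return sim.rnaseq(condition, replicate), sim.truth_introns


def simulate_chip(
    sim: Simulator, mark: str, condition: Literal["wt", "mut"], shape: Optional[str] = None
) -> tuple[AlignmentSet, AlignmentSet]:
    """One ChIP library and its matched input control."""
    return sim.chip(mark, condition, shape=shape), sim.chip_input(condition)
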