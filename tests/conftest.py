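import numpy as np
import pytest

from irshift.annotation_model import GeneModel
from irshift.quantification import AlignmentRecord, AlignmentSet


@pytest.fixture
def simple_gene():
    """Plus-strand gene with three exons at [0,100), [200,300), [400,500)."""
    return GeneModel(
        "gA", "chr1", "+", 0, 500, {"gA.t1": [(0, 100), (200, 300), (400, 500)]}
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        "gB", "chr1", "-", 0, 500, {"gB.t1": [(0, 100), (200, 300), (400, 500)]}
    )


def make_reads(blocks_list, chrom="chr1", strand="+", sample_id="s"):
    records = [AlignmentRecord(chrom, strand, blocks) for blocks in blocks_list]
    return AlignmentSet.from_records(records, sample_id=sample_id)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_toy_genes(rng, n_genes=6, chrom="chrT"):
    """Random, possibly overlapping multi-transcript gene models for oracles."""
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, 3000))
        n_tx = int(rng.integers(1, 4))
        transcripts = {}
        for t in range(n_tx):
            pos = start + int(rng.integers(0, 80))
            exons = []
            for _ in range(int(rng.integers(2, 5))):
                length = int(rng.integers(20, 120))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(15, 150))
            transcripts[f"g{i}.t{t}"] = exons
        span_start = min(e[0][0] for e in transcripts.values())
        span_end = max(e[-1][1] for e in transcripts.values())
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", chrom, strand, span_start, span_end, transcripts))
    return genes


def brute_force_units(genes, exon_universe="all_genes", min_fragment=10):
    """Per-base set-arithmetic oracle for unit construction."""
    exon_bases_by_chrom: dict[str, set] = {}
    intron_bases_by_chrom: dict[str, set] = {}
    per_gene = {}
    for g in genes:
        ex = set()
        intr = set()
        for chain in g.transcripts.values():
            chain = sorted(chain)
            for s, e in chain:
                ex.update(range(s, e))
            for (s1, e1), (s2, e2) in zip(chain, chain[1:]):
                intr.update(range(e1, s2))
        per_gene[g.gene_id] = (ex, intr)
        exon_bases_by_chrom.setdefault(g.chrom, set()).update(ex)
        intron_bases_by_chrom.setdefault(g.chrom, set()).update(intr)

    def runs(bases):
        out = []
        for b in sorted(bases):
            if out and b == out[-1][1]:
                out[-1][1] = b + 1
            else:
                out.append([b, b + 1])
        return [(s, e) for s, e in out if e - s >= min_fragment]

    result = {}
    for g in genes:
        ex, intr = per_gene[g.gene_id]
        if exon_universe == "all_genes":
            ex_uni = exon_bases_by_chrom[g.chrom]
            intr_uni = intron_bases_by_chrom[g.chrom]
        else:
            ex_uni, intr_uni = ex, intr
        result[g.gene_id] = {
            "introns": runs(intr - ex_uni),
            "exons": runs(ex - intr_uni),
        }
    return result
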