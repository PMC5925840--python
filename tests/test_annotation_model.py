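import numpy as np
import pytest

from irshift.annotation_model import (
    AnnotationParseError,
    GeneModel,
    build_units,
    parse_annotation,
    relative_position,
    write_units_bed,
)

from conftest import brute_force_units, random_toy_genes


# -- parsing ----------------------------------------------------------------


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return str(p)


def test_parse_gtf_coordinate_conversion(tmp_path):
    path = _write(tmp_path, "a.gtf", [
        'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
    ])
    genes = parse_annotation(path)
    assert len(genes) == 1
    g = genes[0]
    assert (g.span_start, g.span_end) == (0, 300)
    assert g.transcripts["t1"] == [(0, 100), (200, 300)]


def test_parse_two_transcripts_one_gene(tmp_path):
    path = _write(tmp_path, "a.gtf", [
        'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        'chr1\tsrc\texon\t51\t150\t.\t+\t.\tgene_id "g1"; transcript_id "t2";',
    ])
    genes = parse_annotation(path)
    assert len(genes) == 1
    assert set(genes[0].transcripts) == {"t1", "t2"}


def test_parse_gff3(tmp_path):
    path = _write(tmp_path, "a.gff3", [
        "chr1\tsrc\tmRNA\t1\t300\t.\t-\t.\tID=t1;Parent=g1",
        "chr1\tsrc\texon\t1\t100\t.\t-\t.\tParent=t1",
        "chr1\tsrc\texon\t201\t300\t.\t-\t.\tParent=t1",
    ])
    genes = parse_annotation(path)
    assert len(genes) == 1
    assert genes[0].gene_id == "g1"
    assert genes[0].strand == "-"
    assert genes[0].tss == 300  # minus strand: TSS at the span_end side


def test_parse_malformed_line_names_lineno(tmp_path):
    path = _write(tmp_path, "a.gtf", [
        'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
        "chr1\tbroken line",
    ])
    with pytest.raises(AnnotationParseError, match=":2:"):
        parse_annotation(path)


def test_parse_bad_coordinates(tmp_path):
    path = _write(tmp_path, "a.gtf", [
        'chr1\tsrc\texon\tX\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";',
    ])
    with pytest.raises(AnnotationParseError, match=":1:"):
        parse_annotation(path)


# -- gene model invariants --------------------------------------------------


def test_minus_strand_tss_tts(minus_gene):
    assert minus_gene.tss == 500
    assert minus_gene.tts == 0


def test_invalid_span_rejected():
    with pytest.raises(ValueError):
        GeneModel("g", "chr1", "+", 100, 100, {})


# -- unit construction ------------------------------------------------------


def test_single_transcript_introns(simple_gene):
    introns, exons = build_units([simple_gene])
    assert [(u.start, u.end) for u in introns] == [(100, 200), (300, 400)]
    assert [(u.start, u.end) for u in exons] == [(0, 100), (200, 300), (400, 500)]


def test_overlapping_transcript_fragments_introns():
    # second transcript exon [150, 250) splits the first intron and removes
    # part of it; brute-force per-base subtraction is the oracle
    g = GeneModel(
        "g1", "chr1", "+", 0, 500,
        {"t1": [(0, 100), (200, 300), (400, 500)], "t2": [(150, 250)]},
    )
    introns, _ = build_units([g])
    got = [(u.start, u.end) for u in introns]
    oracle = brute_force_units([g])["g1"]["introns"]
    assert got == oracle == [(100, 150), (300, 400)]


def test_full_exon_overlap_removes_introns():
    g = GeneModel(
        "g1", "chr1", "+", 0, 500,
        {"t1": [(0, 100), (200, 300), (400, 500)], "t2": [(90, 410)]},
    )
    introns, _ = build_units([g])
    assert introns == []


def test_single_exon_gene_no_introns():
    g = GeneModel("g1", "chr1", "+", 0, 100, {"t1": [(0, 100)]})
    introns, exons = build_units([g])
    assert introns == []
    assert len(exons) == 1


def test_min_fragment_dropped():
    g = GeneModel(
        "g1", "chr1", "+", 0, 300,
        {"t1": [(0, 100), (105, 200), (295, 300)]},
    )
    introns, _ = build_units([g], min_fragment=10)
    assert [(u.start, u.end) for u in introns] == [(200, 295)]


def test_cross_gene_exon_universe():
    g1 = GeneModel("g1", "chr1", "+", 0, 300, {"t1": [(0, 100), (200, 300)]})
    g2 = GeneModel("g2", "chr1", "-", 120, 480, {"t2": [(120, 180), (400, 480)]})
    introns_all, _ = build_units([g1, g2], exon_universe="all_genes")
    g1_introns = [(u.start, u.end) for u in introns_all if u.gene_id == "g1"]
    assert g1_introns == [(100, 120), (180, 200)]
    introns_same, _ = build_units([g1, g2], exon_universe="same_gene")
    g1_same = [(u.start, u.end) for u in introns_same if u.gene_id == "g1"]
    assert g1_same == [(100, 200)]


def test_flanking_exons(simple_gene):
    introns, _ = build_units([simple_gene])
    first = introns[0]
    assert first.left_flank.end == 100
    assert first.right_flank.start == 200


def test_units_disjoint_and_cover_span(simple_gene):
    introns, exons = build_units([simple_gene])
    bases_i = {b for u in introns for b in range(u.start, u.end)}
    bases_e = {b for u in exons for b in range(u.start, u.end)}
    assert not bases_i & bases_e
    assert bases_i | bases_e == set(range(0, 500))


def test_brute_force_oracle_random(rng):
    genes = random_toy_genes(rng, n_genes=8)
    introns, exons = build_units(genes)
    oracle = brute_force_units(genes)
    for g in genes:
        got_i = [(u.start, u.end) for u in introns if u.gene_id == g.gene_id]
        got_e = [(u.start, u.end) for u in exons if u.gene_id == g.gene_id]
        assert got_i == oracle[g.gene_id]["introns"], g.gene_id
        assert got_e == oracle[g.gene_id]["exons"], g.gene_id


# -- relative position ------------------------------------------------------


def test_relative_position_examples(simple_gene, minus_gene):
    assert relative_position((100, 200), simple_gene) == pytest.approx(0.3)
    assert relative_position((100, 200), minus_gene) == pytest.approx(0.7)
    assert relative_position((0, 500), simple_gene) == pytest.approx(0.5)


def test_relative_position_five_prime_mode(simple_gene, minus_gene):
    assert relative_position((100, 200), simple_gene, "five_prime") == pytest.approx(0.2)
    assert relative_position((100, 200), minus_gene, "five_prime") == pytest.approx(0.6)


def test_strand_mirror_property(rng):
    """Reversing an annotation around its midpoint and flipping strand
    mirrors every intron's rel_position."""
    genes = random_toy_genes(rng, n_genes=6)
    introns, _ = build_units(genes, exon_universe="same_gene")
    mirrored = []
    for g in genes:
        pivot = g.span_start + g.span_end
        tx = {
            t: sorted((pivot - e, pivot - s) for s, e in chain)
            for t, chain in g.transcripts.items()
        }
        mirrored.append(
            GeneModel(
                g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                g.span_start, g.span_end, tx,
            )
        )
    m_introns, _ = build_units(mirrored, exon_universe="same_gene")
    orig = sorted((u.gene_id, round(u.rel_position, 9)) for u in introns)
    mirr = sorted((u.gene_id, round(u.rel_position, 9)) for u in m_introns)
    assert orig == mirr


def test_write_units_bed(tmp_path, simple_gene):
    introns, exons = build_units([simple_gene])
    ip, ep = tmp_path / "i.bed", tmp_path / "e.bed"
    write_units_bed(introns, exons, str(ip), str(ep))
    lines = ip.read_text().strip().split("\n")
    assert len(lines) == 2
    chrom, s, e, name, score, strand = lines[0].split("\t")
    assert (chrom, s, e, name, strand) == ("chr1", "100", "200", "gA:i0", "+")
    assert score == "300"  # rel_position 0.3 x 1000
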