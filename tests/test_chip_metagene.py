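import numpy as np
import pytest

from irshift.annotation_model import GeneModel
from irshift.chip_metagene import (
    BinLayout,
    BinProfile,
    ShortGeneError,
    aggregate_profile,
    bin_coverage,
    call_shift,
    classify_shift_types,
    diff_matrix,
    profile_genes,
    shift_calls_frame,
    signal_at_introns,
    signal_expression_association,
    _bin_means,
    _raw_profile,
)
from irshift.quantification import AlignmentSet

LAYOUT = BinLayout()


def _gene(start=10_000, length=3000, strand="+", gid="g"):
    return GeneModel(gid, "chr1", strand, start, start + length,
                     {f"{gid}.t": [(start, start + length)]})


def _uniform_reads(lo, hi, n, read_len=50, seed=0):
    rng = np.random.default_rng(seed)
    starts = rng.integers(lo, hi, size=n)
    return AlignmentSet.from_arrays("chr1", starts, starts + read_len, n_reads=n)


# -- binning ----------------------------------------------------------------


def test_bin_means_constant_coverage():
    assert np.allclose(_bin_means(np.full(3000, 2.0), 300), 2.0)


def test_bin_means_fractional_edges():
    # 10 bases into 4 bins of width 2.5; coverage = base index
    cov = np.arange(10, dtype=float)
    means = _bin_means(cov, 4)
    # integral of the step function reproduces per-base totals
    assert np.sum(means * 2.5) == pytest.approx(cov.sum())


def test_raw_profile_conserves_coverage():
    """Pre-normalization bin sums equal per-base coverage totals."""
    gene = _gene(length=2994)  # body not divisible by 300
    reads = _uniform_reads(gene.span_start - 2000, gene.span_end + 2000, 5000)
    prof = _raw_profile(reads, gene, LAYOUT)
    body_bins = prof[100:400]
    body_cov = reads.coverage("chr1", gene.span_start, gene.span_end)
    assert np.sum(body_bins) * (gene.length / 300) == pytest.approx(body_cov.sum(), rel=1e-9)
    flank_cov = reads.coverage("chr1", gene.span_start - 2000, gene.span_start)
    assert np.sum(prof[:100]) * 20 == pytest.approx(flank_cov.sum(), rel=1e-9)


def test_perfect_calibration_zero_profile():
    gene = _gene()
    reads = _uniform_reads(0, 30_000, 40_000, seed=1)
    prof = bin_coverage(reads, reads, gene)  # chip == input
    assert np.allclose(prof.bins, 0.0)


def test_chip_twice_input_flat_positive():
    gene = _gene()
    chip = _uniform_reads(0, 30_000, 40_000, seed=2)
    inp = _uniform_reads(0, 30_000, 20_000, seed=3)
    # equal *library* normalization: chip has 2x reads -> positive profile
    prof = bin_coverage(chip, inp, gene, norm_reads=1e6)
    scale_chip = 1e6 / chip.n_reads
    scale_inp = 1e6 / inp.n_reads
    # densities equal after per-library scaling... use raw scaling instead
    prof2 = BinProfile(gene.gene_id,
                       _raw_profile(chip, gene, LAYOUT) - _raw_profile(inp, gene, LAYOUT))
    assert (prof2.bins > 0).mean() > 0.95


def test_minus_strand_profile_mirrored():
    gene_p = _gene(strand="+")
    gene_m = _gene(strand="-")
    rng = np.random.default_rng(4)
    # 3'-weighted genomic coverage: reads only in the right half
    starts = rng.integers(gene_p.span_start + 1500, gene_p.span_end, size=5000)
    reads = AlignmentSet.from_arrays("chr1", starts, starts + 50, n_reads=5000)
    prof_p = bin_coverage(reads, None, gene_p, calibration="none")
    prof_m = bin_coverage(reads, None, gene_m, calibration="none")
    assert np.allclose(prof_p.bins, prof_m.bins[::-1])
    # minus-strand gene sees the signal at its TSS (front) side
    body_m = prof_m.bins[100:400]
    assert body_m[:150].sum() > body_m[150:].sum()


def test_short_gene_excluded():
    gene = _gene(length=400)
    reads = _uniform_reads(0, 30_000, 1000)
    with pytest.raises(ShortGeneError):
        bin_coverage(reads, reads, gene)
    profiles, excluded = profile_genes(reads, reads, [gene])
    assert profiles == {} and "g" in excluded


def test_missing_input_error():
    with pytest.raises(ValueError, match="input"):
        bin_coverage(_uniform_reads(0, 30_000, 100), None, _gene())


# -- aggregation / diff matrix ----------------------------------------------


def test_aggregate_single_profile_identity():
    p = BinProfile("g", np.arange(500.0))
    agg, n = aggregate_profile([p])
    assert n == 1 and np.allclose(agg, p.bins)


def test_aggregate_cancellation():
    agg, n = aggregate_profile(
        [BinProfile("a", np.ones(500)), BinProfile("b", -np.ones(500))]
    )
    assert np.allclose(agg, 0.0)


def test_aggregate_matches_direct_mean(rng):
    profiles = [BinProfile(f"g{i}", rng.normal(size=500)) for i in range(7)]
    agg, _ = aggregate_profile(profiles)
    assert np.allclose(agg, np.mean([p.bins for p in profiles], axis=0))


def test_diff_matrix_identical_conditions():
    profs = {f"g{i}": BinProfile(f"g{i}", np.full(500, float(i))) for i in range(4)}
    dm = diff_matrix(profs, profs)
    assert np.allclose(dm.matrix, 0.0)
    assert (dm.sort_keys == 0).all()


def test_diff_matrix_sorting_and_keys():
    wt = {g: BinProfile(g, np.zeros(500)) for g in ("a", "b", "c")}
    mut = {
        "a": BinProfile("a", np.zeros(500)),
        "b": BinProfile("b", np.ones(500)),  # all 300 body bins positive
        "c": BinProfile("c", np.concatenate([np.zeros(200), np.ones(100), np.zeros(200)])),
    }
    dm = diff_matrix(mut, wt)
    assert dm.gene_order == ["b", "c", "a"]
    assert list(dm.sort_keys) == [300, 100, 0]


def test_diff_matrix_ordering_matches_counting_oracle(rng):
    wt = {f"g{i}": BinProfile(f"g{i}", rng.normal(size=500)) for i in range(20)}
    mut = {f"g{i}": BinProfile(f"g{i}", rng.normal(size=500)) for i in range(20)}
    dm = diff_matrix(mut, wt)
    oracle = sorted(
        ((-(int(np.sum((mut[g].bins - wt[g].bins)[100:400] > 0))), g) for g in wt),
    )
    assert dm.gene_order == [g for _, g in oracle]


def test_diff_matrix_gene_mismatch():
    wt = {"a": BinProfile("a", np.zeros(500))}
    mut = {"b": BinProfile("b", np.zeros(500))}
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        diff_matrix(mut, wt)


# -- shift calling ----------------------------------------------------------


def _row(front_pos, rear_neg):
    """Row with exactly front_pos positive front-half bins and rear_neg
    negative rear-half bins; everything else zero."""
    row = np.zeros(500)
    row[100:100 + front_pos] = 1.0
    row[250:250 + rear_neg] = -1.0
    return row


def test_shift_front_gain_rear_loss():
    row = np.zeros(500)
    row[100:250] = 1.0
    row[250:400] = -1.0
    assert call_shift(row)


def test_all_zeros_not_shifted():
    assert not call_shift(np.zeros(500))


def test_boundary_exactness():
    assert call_shift(_row(45, 45))
    assert not call_shift(_row(44, 45))
    assert not call_shift(_row(45, 44))


def test_flanks_ignored():
    row = _row(45, 45)
    row[:100] = -5.0  # upstream flank strongly negative
    row[400:] = 5.0
    assert call_shift(row)


def test_wrong_length_rejected():
    with pytest.raises(ValueError):
        call_shift(np.zeros(400))


# -- type classification ----------------------------------------------------


def test_classify_types():
    calls = classify_shift_types(
        {"a": True, "b": False, "c": True, "d": False},
        {"a": False, "b": True, "c": True, "d": False},
    )
    types = {c.gene_id: c.type for c in calls}
    assert types == {"a": "I", "b": "II", "c": "III", "d": "IV"}
    df = shift_calls_frame(calls)
    assert set(df.columns) == {"gene_id", "me2_shifted", "me3_shifted", "type"}


def test_classify_mismatched_universe():
    with pytest.raises(ValueError):
        classify_shift_types({"a": True}, {"b": True})


# -- intron signal / expression association ---------------------------------


def _intron_units():
    from irshift.annotation_model import build_units

    g = GeneModel("g", "chr1", "+", 0, 3000,
                  {"t": [(0, 500), (1000, 1500), (2000, 3000)]})
    introns, _ = build_units([g])
    return introns


def test_signal_at_introns_identical_groups():
    introns = _intron_units()
    reads = _uniform_reads(0, 3000, 20_000, seed=5)
    res = signal_at_introns(reads, None, {"up": [introns[0]], "down": [introns[1]]})
    # single-intron groups -> no test, but values computed
    assert set(res["values"]) == {"up", "down"}


def test_signal_at_introns_planted_difference(rng):
    introns = _intron_units()
    up_set = [introns[0]] * 300
    down_set = [introns[1]] * 300
    starts = np.concatenate([
        rng.integers(500, 1000, size=20_000),  # 2x signal over intron 1
        rng.integers(1500, 2000, size=10_000),
    ])
    reads = AlignmentSet.from_arrays("chr1", starts, starts + 50, n_reads=30_000)
    res = signal_at_introns(reads, None, {"up": up_set, "down": down_set})
    assert res["medians"]["up"] > res["medians"]["down"]


def test_signal_at_introns_empty_group():
    with pytest.raises(ValueError, match="empty"):
        signal_at_introns(_uniform_reads(0, 3000, 10), None, {"up": []})


def test_signal_expression_identity_correlation():
    sig = {f"g{i}": float(i) for i in range(50)}
    res = signal_expression_association(sig, sig, n_quantiles=5)
    assert res["spearman_rho"] == pytest.approx(1.0)
    assert (np.diff(res["per_quantile"]["mean_signal"]) > 0).all()


def test_signal_expression_independent(rng):
    sig = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=1000))}
    expr = {f"g{i}": float(v) for i, v in enumerate(rng.lognormal(size=1000))}
    res = signal_expression_association(sig, expr)
    assert abs(res["spearman_rho"]) < 0.1


def test_signal_expression_constant_signal():
    sig = {f"g{i}": 1.0 for i in range(20)}
    expr = {f"g{i}": float(i) for i in range(20)}
    res = signal_expression_association(sig, expr, n_quantiles=4)
    assert res["spearman_rho"] == 0.0


def test_signal_expression_too_few_genes():
    with pytest.raises(ValueError):
        signal_expression_association({"a": 1.0}, {"a": 1.0}, n_quantiles=5)
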