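"""Edge exclusion, imputation, trimming, and the two fitness scales."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import satay_fitness as sf
from satay_fitness import fitness_core as fc


def _profile(reads, rel=None, o_full=None):
    reads = np.asarray(reads, dtype=float)
    rel = np.asarray(rel if rel is not None else [0.5] * len(reads), dtype=float)
    return fc.GeneReadProfile(
        gene_id="G",
        rel_positions=rel,
        reads=reads,
        n_observed=int((reads >= 1).sum()),
        n_edge_excluded=0,
        o_full=o_full if o_full is not None else len(reads),
    )


class TestAssignAndFilter:
    def test_edge_site_excluded_but_counted(self):
        gene = sf.GeneAnnotation("G", "chrI", 100, 1099, "+")
        imap = sf.InsertionMap.from_records([("chrI", 150, 4)])
        prof = fc.assign_and_filter(imap, gene)
        assert prof.n_observed == 0
        assert prof.n_edge_excluded == 1
        assert prof.o_full == 1
        assert len(prof.reads) == 0

    def test_central_site_retained(self):
        gene = sf.GeneAnnotation("G", "chrI", 100, 1099, "+")
        imap = sf.InsertionMap.from_records([("chrI", 600, 4)])
        prof = fc.assign_and_filter(imap, gene)
        assert prof.n_observed == 1
        assert prof.rel_positions[0] == pytest.approx(0.5)
        assert prof.reads.tolist() == [4.0]

    def test_minus_strand_orientation(self):
        # coding-strand relative position is measured from the start codon,
        # which sits at the high coordinate on the minus strand
        gene = sf.GeneAnnotation("G", "chrI", 100, 1099, "-")
        imap = sf.InsertionMap.from_records([("chrI", 950, 4)])
        prof = fc.assign_and_filter(imap, gene)
        assert prof.rel_positions[0] == pytest.approx((1099 - 950) / 1000)
        assert prof.n_observed == 1

    def test_half_open_boundaries_exact(self):
        # gene of length 10000 starting at 1: rel = (pos - 1)/10000
        gene = sf.GeneAnnotation("G", "chrI", 1, 10_000, "+")
        cases = {1000: False, 1001: True, 9000: True, 9001: False}
        for pos, retained in cases.items():
            imap = sf.InsertionMap.from_records([("chrI", pos, 1)])
            prof = fc.assign_and_filter(imap, gene)
            assert (prof.n_observed == 1) is retained, pos

    def test_strand_flip_symmetry(self):
        gene_f = sf.GeneAnnotation("G", "chrI", 1, 10_000, "+")
        gene_r = sf.GeneAnnotation("G", "chrI", 1, 10_000, "-")
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1, 10_001), size=300, replace=False))
        imap = sf.InsertionMap.from_records([("chrI", int(p), 1) for p in pos])
        prof_f = fc.assign_and_filter(imap, gene_f)
        prof_r = fc.assign_and_filter(imap, gene_r)
        assert prof_f.n_observed == prof_r.n_observed
        assert prof_f.n_edge_excluded == prof_r.n_edge_excluded
        # mirrored relative positions describe the same physical sites
        mirrored = np.sort(1.0 - prof_r.rel_positions - 1.0 / gene_r.length)
        assert np.allclose(np.sort(prof_f.rel_positions), mirrored, atol=1e-12)


class TestImputation:
    def test_appends_zero_sites(self):
        prof = _profile([5, 9, 9], o_full=4)  # one edge site observed besides
        out = fc.impute_zero_sites(prof, expected=10)
        assert sorted(out.reads.tolist()) == [0, 0, 0, 0, 0, 0, 5, 9, 9]
        assert out.n_zero_imputed == 6
        assert out.reads.sum() == prof.reads.sum()  # observed reads conserved

    def test_no_zeros_when_observed_exceeds_expected(self):
        prof = _profile([3, 3], o_full=7)
        out = fc.impute_zero_sites(prof, expected=3)
        assert out.reads.tolist() == [3, 3]
        assert out.n_zero_imputed == 0

    def test_central_only_counting_variant(self):
        prof = _profile([3], o_full=5)
        out = fc.impute_zero_sites(prof, expected=4, full_gene=False)
        assert out.n_zero_imputed == 3  # 4 - n_observed(=1)


class TestOutlierTrim:
    def test_extreme_value_removed(self):
        # 20 ones and a 1000: q5 = q95 = 1, threshold 1 -> the 1000 goes
        prof = _profile([1] * 20 + [1000])
        out = fc.trim_outliers(prof)
        assert out.reads.tolist() == [1.0] * 20
        assert out.n_trimmed == 1

    def test_threshold_follows_percentile_convention(self):
        # [1]*9 + [100]: with linear-interpolation percentiles
        # q95 = 1 + 0.55*99 = 55.45, threshold = q95 + 1.5*(q95 - q5) = 137.125,
        # so the 100 is NOT an outlier under the documented convention
        reads = [1.0] * 9 + [100.0]
        q5, q95 = np.percentile(reads, [5, 95])
        assert q95 + 1.5 * (q95 - q5) > 100
        out = fc.trim_outliers(_profile(reads))
        assert out.n_trimmed == 0

    def test_all_equal_nothing_removed(self):
        out = fc.trim_outliers(_profile([7, 7, 7, 7]))
        assert out.reads.tolist() == [7.0] * 4

    def test_all_zero_unchanged(self):
        out = fc.trim_outliers(_profile([0, 0, 0]))
        assert out.reads.tolist() == [0.0, 0.0, 0.0]

    def test_zeros_are_never_trimmed(self):
        prof = _profile([0, 0, 5, 5, 5, 500])
        out = fc.trim_outliers(prof)
        assert (out.reads == 0).sum() == 2


class TestMeanReads:
    @pytest.mark.parametrize(
        "reads,mean",
        [
            ([2, 4, 6], 4.0),
            ([5, 9, 9, 0, 0, 0, 0, 0, 0], 23 / 9),
            ([0, 0, 0, 1], 0.25),
        ],
    )
    def test_examples(self, reads, mean):
        assert fc.mean_reads(_profile(reads)) == pytest.approx(mean)

    def test_empty_profile_is_nan(self):
        assert np.isnan(fc.mean_reads(_profile([])))


class TestMedianScale:
    def test_median_gene_has_fitness_one(self):
        w, mu_ref = fc.fitness_median_scale([2.0, 4.0, 8.0])
        assert mu_ref == pytest.approx(2.0)
        assert w[1] == pytest.approx(1.0)

    def test_squared_median_doubles_fitness(self):
        w, _ = fc.fitness_median_scale([2.0, 4.0, 8.0, 16.0, 16.0])
        # median y = 8 -> gene at 64 = median^2 would have w = 2;
        # here y = 16 = median^(4/3): log2(16)/log2(8) = 4/3
        assert w[-1] == pytest.approx(np.log2(16.0) / np.log2(8.0))
        w2, _ = fc.fitness_median_scale([4.0, 16.0, 4.0])  # median 4, 16 = 4^2
        assert w2[1] == pytest.approx(2.0)

    def test_log_base_invariance(self):
        y = np.array([1.5, 3.0, 20.0, 7.0, 120.0])
        w, _ = fc.fitness_median_scale(y)
        w_nat = np.log(y) / np.median(np.log(y))
        assert np.allclose(w, w_nat, atol=1e-12)

    def test_sub_median_mean_gives_negative_fitness(self):
        w, _ = fc.fitness_median_scale([0.25, 4.0, 8.0])
        assert w[0] < 0

    def test_degenerate_median_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fc.fitness_median_scale([0.5, 1.0, 2.0])


class TestGenerationScale:
    def test_median_is_one(self):
        assert fc.fitness_generation_scale(5.0, 5.0) == pytest.approx(1.0)

    def test_power_identity(self):
        assert fc.fitness_generation_scale(1024 * 3.0, 3.0, t_gen=10) == pytest.approx(2.0)

    def test_zero_mean_gives_zero(self):
        assert fc.fitness_generation_scale(0.0, 5.0) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    y=st.lists(
        st.floats(min_value=1.5, max_value=1e4, allow_nan=False),
        min_size=3,
        max_size=30,
    )
)
def test_fitness_monotone_in_mean_reads(y):
    """Both fitness scales preserve the ordering of the gene means."""
    y = np.asarray(y)
    w_med, _ = fc.fitness_median_scale(y)
    w_gen = fc.fitness_generation_scale(y, float(np.median(y)))
    order = np.argsort(y, kind="stable")
    assert np.all(np.diff(w_med[order]) >= -1e-12)
    assert np.all(np.diff(np.atleast_1d(w_gen)[order]) >= -1e-12)


class TestPipeline:
    def test_status_rule(self, end_to_end):
        res = end_to_end.result
        cfg = res.config
        for rec in res.records:
            prof = res.profiles[rec.gene_id]
            should_be_ok = bool(
                prof.n_after_trim >= cfg.min_usable_sites and prof.reads.sum() > 0
            )
            assert (rec.status == "ok") == should_be_ok

    def test_ok_median_normalisation(self, end_to_end):
        ok = [r for r in end_to_end.result.records if r.status == "ok"]
        w_med = np.array([r.fitness_median_scale for r in ok])
        w_gen = np.array([r.fitness_generation_scale for r in ok])
        gap = np.diff(np.sort(w_med))
        tol = gap.max() if len(w_med) % 2 == 0 else 1e-9
        assert abs(np.median(w_med) - 1.0) <= tol
        gap_g = np.diff(np.sort(w_gen))
        tol_g = gap_g.max() if len(w_gen) % 2 == 0 else 1e-9
        assert abs(np.median(w_gen) - 1.0) <= tol_g

    def test_essential_genes_mostly_low_or_undetermined(self, end_to_end):
        ok = {r.gene_id: r for r in end_to_end.result.records if r.status == "ok"}
        essential = [g for g in end_to_end.genome.genes if g.essential]
        w_ess = [
            ok[g.gene_id].fitness_median_scale for g in essential if g.gene_id in ok
        ]
        # imputed zeros push essential genes far below the neutral peak
        assert np.median(w_ess) < 0.5

    def test_imputation_requires_centromeres(self, end_to_end):
        with pytest.raises(ValueError, match="centromere"):
            fc.estimate_fitness(end_to_end.library, end_to_end.genome.genes, cen=None)
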