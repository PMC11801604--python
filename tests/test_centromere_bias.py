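"""Cumulative insertion curves, the cubic bias fit, and expected counts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import satay_fitness as sf
from satay_fitness import centromere_bias as cb


def _map_one_chrom(positions, reads=None, chrom="chr1"):
    reads = reads if reads is not None else [1] * len(positions)
    return sf.InsertionMap.from_records(
        [(chrom, p, r) for p, r in zip(positions, reads)]
    )


class TestCumulativeCurve:
    def test_right_arm_hand_count(self):
        imap = _map_one_chrom([1300, 1600])
        cen = {"chr1": (1000, 1100)}
        curve = cb.cumulative_insertions(imap, cen, grid_step=100)
        right = curve.arm_counts["chr1:right"]
        # distances are 200 and 500 bp from cen_end
        assert right[curve.grid.tolist().index(200)] == 1
        assert right[curve.grid.tolist().index(500)] == 2

    def test_site_inside_centromere_gets_distance_zero(self):
        imap = _map_one_chrom([1050])
        dists = cb.site_centromere_distances(imap, {"chr1": (1000, 1100)})
        left, right = dists["chr1"]
        assert left.tolist() == [0]
        assert right.tolist() == []

    def test_missing_centromere_lists_chromosome(self):
        imap = _map_one_chrom([10], chrom="chrX")
        with pytest.raises(ValueError, match="chrX"):
            cb.cumulative_insertions(imap, {"chr1": (1, 2)})

    def test_uniform_placement_recovers_linear_curve(self):
        # uniform sites at rate rho: averaged curve ~ rho * r
        rng = np.random.default_rng(0)
        rho, arm = 0.01, 1_000_000
        cen = {"chr1": (arm + 1, arm + 100)}
        pos = np.nonzero(rng.random(arm) < rho)[0] + 1  # left arm only
        imap = _map_one_chrom(pos.tolist())
        curve = cb.cumulative_insertions(imap, cen, grid_step=1_000)
        mid = len(curve.grid) // 2
        slope = curve.mean_counts[mid] / curve.grid[mid]
        assert slope == pytest.approx(rho, rel=0.05)

    def test_arm_average_ignores_exhausted_arms(self):
        # one long arm and one short arm; beyond the short arm's extent the
        # average must follow the long arm alone
        imap = sf.InsertionMap.from_records(
            [("chr1", 5_000, 1), ("chr1", 10_500, 1), ("chr1", 9_000, 1)]
        )
        cen = {"chr1": (6_000, 6_100)}  # left arm extent 1000, right extent 4400
        curve = cb.cumulative_insertions(imap, cen, grid_step=1_000)
        left = curve.arm_counts["chr1:left"]
        idx_3000 = curve.grid.tolist().index(3_000)
        assert np.isnan(left[idx_3000])
        right = curve.arm_counts["chr1:right"]
        assert curve.mean_counts[idx_3000] == right[idx_3000]


def _curve_from_function(fn, r_max=400_000, step=1_000):
    grid = np.arange(0, r_max + step, step, dtype=np.int64)
    mean = fn(grid.astype(float))
    return cb.CumulativeCurve(
        grid=grid, arm_counts={"a:left": mean.copy()}, mean_counts=mean, grid_step=step
    )


class TestBiasFit:
    def test_linear_curve_recovers_flat_rate(self):
        curve = _curve_from_function(lambda r: 0.1 * r)
        model = cb.fit_bias_model(curve)
        a0, a1, a2, a3 = model.coefficients
        assert a1 == pytest.approx(0.1, abs=1e-9)
        assert abs(a2) < 1e-12 and abs(a3) < 1e-16
        r = np.array([0.0, 50_000.0, 199_999.0, 200_000.0, 1e7])
        assert np.allclose(model.rate(r), 0.1, rtol=1e-6)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(3)
        truth = np.array([5.0, 0.08, -2e-7, 4e-13])  # a0..a3 in bp units

        def fn(r):
            return truth[0] + truth[1] * r + truth[2] * r**2 + truth[3] * r**3

        grid = np.arange(0, 401_000, 1_000, dtype=np.int64)
        noisy = fn(grid.astype(float)) + rng.normal(0, 5.0, len(grid))
        curve = cb.CumulativeCurve(
            grid=grid, arm_counts={}, mean_counts=noisy, grid_step=1_000
        )
        model = cb.fit_bias_model(curve)
        # independent oracle: closed-form normal equations on the same
        # rescaled basis, converted back to bp units
        x = grid / cb.R_SCALE
        design = np.vander(x, 4, increasing=True)
        oracle_scaled = np.linalg.solve(design.T @ design, design.T @ noisy)
        oracle = oracle_scaled / cb.R_SCALE ** np.arange(4)
        assert np.allclose(model.coefficients, oracle, rtol=1e-8)

    def test_rate_constant_and_continuous_beyond_cutoff(self):
        curve = _curve_from_function(lambda r: 0.09 * r - 4e-8 * r**2 + 5e-14 * r**3)
        model = cb.fit_bias_model(curve)
        assert model.rate(200_000) == model.lambda_plateau
        assert model.rate(350_000) == model.lambda_plateau
        assert model.rate(10**9) == model.lambda_plateau
        # continuity: polynomial derivative just below the cutoff meets the plateau
        assert model.rate(199_999) == pytest.approx(model.lambda_plateau, rel=1e-3)

    def test_negative_rate_raises(self):
        # a cumulative curve that flattens hard makes the cubic derivative
        # dip below zero within the fit range
        curve = _curve_from_function(lambda r: np.minimum(r, 60_000.0) * 0.1)
        with pytest.raises(cb.BiasFitError, match="negative"):
            cb.fit_bias_model(curve)

    def test_short_curve_warns(self):
        curve = _curve_from_function(lambda r: 0.1 * r, r_max=150_000)
        with pytest.warns(UserWarning, match="available range"):
            cb.fit_bias_model(curve)

    def test_recovers_simulated_decaying_rate(self):
        # forward-simulate the pericentromeric elevation (0.12 -> 0.067 bp^-1)
        # and recover the rates from the fitted model
        genome = sf.simulate_genome(n_chrom=2, arm_length=450_000, n_genes=0, seed=4)
        truth = sf.SyntheticTruth(growth_rate={}, alpha=0.0, seed=4)
        rng = np.random.default_rng(4)
        from satay_fitness.synthetic_data import place_insertions

        chrom_idx, pos, _ = place_insertions(genome, truth, rng)
        chroms = sorted(genome.chrom_lengths)
        imap = sf.InsertionMap(
            sites={
                c: (
                    pos[chrom_idx == i].astype(np.int64),
                    np.ones((chrom_idx == i).sum(), dtype=np.int64),
                )
                for i, c in enumerate(chroms)
            }
        )
        curve = cb.cumulative_insertions(imap, genome.centromeres)
        model = cb.fit_bias_model(curve)
        assert model.rate(0) == pytest.approx(truth.rate_near, rel=0.15)
        assert model.lambda_plateau == pytest.approx(truth.rate_plateau, rel=0.10)


class TestExpectedInsertions:
    def test_flat_rate_times_length(self, flat_bias_model):
        gene = sf.GeneAnnotation("G", "chr1", 1001, 2000)
        assert cb.expected_insertions(gene, {"chr1": (1, 10)}, flat_bias_model) == 100

    def test_floor_rule(self):
        model = sf.BiasModel((0.0, 0.0667, 0.0, 0.0), 200_000, 0.0667, 0.0, 400_000)
        gene = sf.GeneAnnotation("G", "chr1", 1001, 1100)  # L = 100
        assert cb.expected_insertions(gene, {"chr1": (1, 10)}, model) == 6

    def test_distal_gene_uses_plateau_exactly(self):
        model = sf.BiasModel((0.0, 0.2, 0.0, 0.0), 200_000, 0.05, 0.0, 400_000)
        gene = sf.GeneAnnotation("G", "chr1", 299_501, 300_500)  # center at 300 kb
        expected = cb.expected_insertions(gene, {"chr1": (1, 100)}, model)
        assert expected == int(np.floor(0.05 * 1000))

    def test_gene_center_distance_uses_nearer_edge(self):
        cen = {"chr1": (10_000, 10_200)}
        left = sf.GeneAnnotation("L", "chr1", 7_000, 7_999)  # center 7499
        right = sf.GeneAnnotation("R", "chr1", 12_001, 13_000)  # center 12500
        assert cb.gene_centromere_distance(left, cen) == 10_000 - 7_499
        assert cb.gene_centromere_distance(right, cen) == 12_500 - 10_200
        inside = sf.GeneAnnotation("I", "chr1", 10_050, 10_149)
        assert cb.gene_centromere_distance(inside, cen) == 0


class TestUnobservedSites:
    @pytest.mark.parametrize("expected,observed,zeros", [(10, 4, 6), (3, 7, 0), (0, 0, 0)])
    def test_examples(self, expected, observed, zeros):
        assert cb.unobserved_sites(expected, observed) == zeros

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        e=st.integers(min_value=0, max_value=10_000),
        o=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_brute_force(self, e, o):
        brute = e - o if e > o else 0
        assert cb.unobserved_sites(e, o) == brute

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cb.unobserved_sites(-1, 0)
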