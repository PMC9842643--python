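"""Likelihood machinery: NB pmf, f0 integration, MLE, p-values, FDR."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

from barfit.containers import GeneBarcodeSet, MeanFitnessSeries
from barfit.containers import serial_dilution_timepoints
from barfit.error_model import NoiseModel
from barfit.inference import (
    LikelihoodCurve,
    SGrid,
    barcode_curve,
    combine_replicates,
    estimate_from_curve,
    fdr_correct,
    integrated_loglik,
    mle_fitness,
    nb_loglik,
    neutrality_pvalue,
)


class TestNbLoglik:
    def test_pmf_normalizes_to_one(self):
        r = np.arange(501)
        total = np.exp(nb_loglik(r, 3.0, 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_poisson_limit_at_zero(self):
        assert nb_loglik(0, 2.0, 1.0) == pytest.approx(-2.0)
        assert nb_loglik(0, 2.0, 1.0 + 1e-9) == pytest.approx(-2.0)

    def test_matches_direct_gamma_form(self):
        # independent evaluation of the Gamma-form pmf
        r, mu, c = 5, 5.0, 2.0
        m = mu / (c - 1)
        direct = (
            gammaln(r + m) - gammaln(m) - gammaln(r + 1)
            + r * np.log(c - 1) - (r + m) * np.log(c)
        )
        assert nb_loglik(r, mu, c) == pytest.approx(direct, abs=1e-12)

    def test_matches_scipy_nbinom(self):
        # cross-check against scipy's NB(n, p) parametrization
        rng = np.random.default_rng(0)
        for _ in range(50):
            mu = rng.uniform(0.5, 300)
            c = rng.uniform(1.01, 5)
            r = rng.integers(0, 400)
            n, p = mu / (c - 1), 1.0 / c
            assert nb_loglik(r, mu, c) == pytest.approx(
                nbinom.logpmf(r, n, p), abs=1e-9
            )

    def test_poisson_branch_matches_scipy(self):
        assert nb_loglik(7, 4.0, 1.0) == pytest.approx(
            poisson.logpmf(7, 4.0), abs=1e-12
        )

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            nb_loglik(-1, 2.0, 2.0)

    def test_rejects_underdispersion(self):
        with pytest.raises(ValueError):
            nb_loglik(1, 2.0, 0.9)


def simple_setup(n_t=5, R=2e7):
    meta = serial_dilution_timepoints(n_t - 1, total_reads=int(R))
    gens = meta["generations"].to_numpy(float)
    noise = NoiseModel.from_parameters(2e-8, 1e8, np.full(n_t, R), np.arange(n_t))
    return gens, noise, MeanFitnessSeries.zero(gens)


class TestIntegratedLoglik:
    def test_single_timepoint_is_flat_in_s(self):
        gens, noise, xb = simple_setup()
        s = np.linspace(-0.1, 0.1, 21)
        mask = np.array([True] + [False] * 4)
        ll = integrated_loglik(s, np.array([400, 0, 0, 0, 0]), mask, noise, xb)
        assert np.ptp(ll) < 1e-9

    def test_noiseless_trajectory_peaks_at_truth(self):
        gens, noise, xb = simple_setup()
        s_true, f0 = 0.05, 2e-5
        counts = np.rint(2e7 * f0 * np.exp(s_true * gens)).astype(int)
        curve = barcode_curve(
            counts, np.ones(5, bool), noise, xb, SGrid(-0.1, 0.1, 5e-4)
        )
        assert estimate_from_curve(curve).s_hat == pytest.approx(
            s_true, abs=5e-4
        )

    def test_information_scales_with_depth(self):
        gens, noise, xb = simple_setup()
        counts = np.rint(2e7 * 2e-5 * np.exp(0.03 * gens)).astype(int)
        noise2 = NoiseModel.from_parameters(
            1e-8, 2e8, np.full(5, 4e7), np.arange(5)
        )  # same c_t, doubled depth
        assert np.allclose(noise2.c, noise.c)
        c1 = barcode_curve(counts, np.ones(5, bool), noise, xb,
                           SGrid(-0.1, 0.1, 5e-4))
        c2 = barcode_curve(2 * counts, np.ones(5, bool), noise2, xb,
                           SGrid(-0.1, 0.1, 5e-4))
        e1, e2 = estimate_from_curve(c1), estimate_from_curve(c2)
        assert e2.s_hat == pytest.approx(e1.s_hat, abs=2 * 5e-4)
        assert e2.se < e1.se

    def test_grid_density_insensitivity(self):
        gens, noise, xb = simple_setup()
        counts = np.rint(2e7 * 2e-5 * np.exp(0.02 * gens)).astype(int)
        a = barcode_curve(counts, np.ones(5, bool), noise, xb,
                          SGrid(-0.1, 0.1, 5e-4), n_f0=61)
        b = barcode_curve(counts, np.ones(5, bool), noise, xb,
                          SGrid(-0.1, 0.1, 5e-4), n_f0=122)
        assert estimate_from_curve(a).s_hat == pytest.approx(
            estimate_from_curve(b).s_hat, abs=1e-3
        )


class TestMleFitness:
    def test_constant_frequency_gene_is_neutral(self):
        gens, noise, xb = simple_setup()
        import pandas as pd

        counts = pd.DataFrame(
            {f"t{i}": [400, 250, 318, 520] for i in range(5)},
            index=[f"b{i}" for i in range(4)],
        )
        gene = GeneBarcodeSet("g", counts)
        est, _ = mle_fitness(gene, noise, xb, SGrid(-0.1, 0.1, 5e-4))
        assert est.s_hat == pytest.approx(0.0, abs=5e-4)

    def test_recovery_within_two_se_on_synthetic_genes(self, fitted, s_true_map):
        df, _ = fitted
        s_map = s_true_map
        z = np.array(
            [abs(df.loc[g, "s_hat"] - s_map[g]) / df.loc[g, "se"] for g in df.index]
        )
        assert np.mean(z <= 2) >= 10 / 12  # small-sample smoke check
        assert np.median(z) < 1.5

    def test_significance_calls_match_truth(self, fitted, s_true_map):
        df, _ = fitted
        called = df["significant"]
        for g, s in s_true_map.items():
            if abs(s) >= 0.02:
                assert called.loc[g], f"{g} (s={s}) should be significant"

    def test_loglik_shift_invariance(self, fitted):
        df, curves = fitted
        g = df.index[0]
        curve = curves[g]
        shifted = LikelihoodCurve(curve.s, curve.loglik + 123.4)
        a, b = estimate_from_curve(curve), estimate_from_curve(shifted)
        assert a.s_hat == pytest.approx(b.s_hat, abs=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-9)
        assert a.p == pytest.approx(b.p, abs=1e-12)


class TestCombineReplicates:
    def gaussian_curve(self, center, curvature=5e5, grid=None):
        s = grid if grid is not None else SGrid(-0.1, 0.1, 5e-4).values()
        return LikelihoodCurve(s, -0.5 * curvature * (s - center) ** 2)

    def test_self_combination_doubles_curvature(self):
        c = self.gaussian_curve(0.02)
        comb = combine_replicates([c, c])
        a, b = estimate_from_curve(c), estimate_from_curve(comb)
        assert b.s_hat == pytest.approx(a.s_hat, abs=1e-9)
        assert b.se == pytest.approx(a.se / np.sqrt(2), rel=1e-6)

    def test_flat_curve_is_identity(self):
        c = self.gaussian_curve(0.01)
        flat = LikelihoodCurve(c.s, np.zeros_like(c.s))
        comb = combine_replicates([c, flat])
        assert np.allclose(comb.loglik, c.loglik)

    def test_equal_curvature_peaks_average(self):
        comb = combine_replicates(
            [self.gaussian_curve(0.01), self.gaussian_curve(0.03)]
        )
        assert estimate_from_curve(comb).s_hat == pytest.approx(0.02, abs=1e-9)

    def test_replicate_combination_shrinks_se(
        self, experiment, processed, noise_model, xbar, grid
    ):
        from barfit.error_model import fit_noise_model
        from barfit.mean_fitness import mean_fitness_series
        from barfit.processing import process_experiment

        g = "g0001"
        genes1, _ = processed
        est1, curve1 = mle_fitness(genes1[g], noise_model, xbar, grid)
        genes2, inter2 = process_experiment(
            experiment["tables"][1], experiment["pool"], merge_errors=False
        )
        nm2 = fit_noise_model(inter2, n_boot=20, rng=np.random.default_rng(1))
        xb2 = mean_fitness_series(inter2, rng=np.random.default_rng(1))
        est2, curve2 = mle_fitness(genes2[g], nm2, xb2, grid)
        comb = estimate_from_curve(combine_replicates([curve1, curve2]))
        assert comb.se < est1.se and comb.se < est2.se

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_replicates([])


class TestNeutralityPvalue:
    def test_flat_curve_gives_zero(self):
        s = SGrid(-0.05, 0.05, 1e-3).values()
        assert neutrality_pvalue(LikelihoodCurve(s, np.zeros_like(s))) == 0.0

    def test_matches_bruteforce_discretized_definition(self):
        rng = np.random.default_rng(8)
        s = SGrid(-0.05, 0.05, 1e-3).values()
        ll = -0.5 * 3e4 * (s - 0.012) ** 2 + rng.normal(0, 0.1, size=len(s))
        curve = LikelihoodCurve(s, ll)
        # independent evaluation straight from the definition
        post = np.exp(ll - ll.max())
        post /= post.sum()
        ll0 = np.interp(0.0, s, ll)
        expected = post[(ll0 - ll) > 0].sum()
        assert neutrality_pvalue(curve) == pytest.approx(expected, abs=1e-12)

    def test_strong_effect_gives_tiny_p(self):
        s = SGrid(-0.1, 0.1, 5e-4).values()
        se = 0.002
        ll = -0.5 * ((s - 10 * se) / se) ** 2
        assert neutrality_pvalue(LikelihoodCurve(s, ll)) < 1e-6

    def test_neutral_peak_gives_large_p(self):
        # peak exactly at 0: p = 1 minus the posterior mass of the s=0
        # grid point itself, which is step * phi(0)/sigma
        s = SGrid(-0.1, 0.1, 5e-4).values()
        sigma = 0.002
        ll = -0.5 * (s / sigma) ** 2
        expected = 1.0 - 5e-4 / (sigma * np.sqrt(2 * np.pi))
        assert neutrality_pvalue(LikelihoodCurve(s, ll)) == pytest.approx(
            expected, abs=0.005
        )

    def test_grid_must_include_zero(self):
        s = np.linspace(0.01, 0.05, 11)
        with pytest.raises(ValueError):
            neutrality_pvalue(LikelihoodCurve(s, np.zeros_like(s)))


class TestFdrCorrect:
    def test_hand_computed_step_up(self):
        # thresholds i*alpha/4 = .0125, .025, .0375, .05: the first three
        # pass, p=0.2 fails
        q, reject = fdr_correct([0.01, 0.02, 0.03, 0.2])
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_rejects_nothing(self):
        _, reject = fdr_correct([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_small_p_rejected(self):
        _, reject = fdr_correct([0.001])
        assert reject.tolist() == [True]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


def test_generations_per_cycle_identity():
    from barfit.containers import generations_per_cycle

    assert generations_per_cycle(100) == np.log2(100)
    meta = serial_dilution_timepoints(3, dilution=100)
    assert np.allclose(np.diff(meta["generations"]), np.log2(100))
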