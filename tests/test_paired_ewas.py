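import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinmeth import (
    MethSimConfig,
    ValidationError,
    adjust_bh,
    beta_to_m,
    call_dmps,
    estimate_surrogates,
    fit_moderated,
    pair_differences,
    simulate_twin_methylation,
)
from twinmeth.paired_ewas import PairDiffMatrix, _trigamma_inverse

from conftest import make_beta_matrix, make_design


def diff_matrix(values: np.ndarray) -> PairDiffMatrix:
    return PairDiffMatrix(pd.DataFrame(np.asarray(values, float)))


class TestBetaToM:
    @pytest.mark.parametrize(
        "beta,expected",
        [
            (0.5, 0.0),
            (0.8, 2.0),
            (0.0, math.log2(0.001 / 0.999)),  # clipped at epsilon = 1e-3
        ],
    )
    def test_known_values(self, beta, expected):
        bm = make_beta_matrix(np.array([[beta, beta]]))
        m = beta_to_m(bm, epsilon=1e-3)
        assert m.m.iloc[0, 0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 0.5, -0.1, 0.7])
    def test_invalid_epsilon_rejected(self, eps):
        bm = make_beta_matrix(np.array([[0.5, 0.5]]))
        with pytest.raises(ValidationError):
            beta_to_m(bm, epsilon=eps)


class TestPairDifferences:
    def test_identical_twins_give_zero_differences(self):
        d = make_design(3)
        rng = np.random.default_rng(0)
        col = rng.normal(size=20)
        m = pd.DataFrame({s: col for s in d.sample_ids})
        out = pair_differences(m, d)
        assert np.abs(out.d.to_numpy()).max() == 0

    def test_swapping_affection_negates_that_column(self):
        d = make_design(3)
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(20, 6)), columns=d.sample_ids)
        base = pair_differences(m, d)
        t = d.table.copy()
        t.loc[["P2_A", "P2_U"], "affected"] = [False, True]
        from twinmeth import TwinDesign

        flipped = pair_differences(m, TwinDesign(t))
        np.testing.assert_allclose(flipped.d["P2"], -base.d["P2"])
        np.testing.assert_allclose(flipped.d["P1"], base.d["P1"])

    def test_seven_pairs_give_seven_columns(self):
        d = make_design(7)
        m = pd.DataFrame(np.zeros((5, 14)), columns=d.sample_ids)
        out = pair_differences(m, d)
        assert out.d.shape == (5, 7)
        assert out.n_pairs == 7

    def test_missing_sample_rejected(self):
        d = make_design(3)
        m = pd.DataFrame(np.zeros((5, 5)), columns=list(d.sample_ids)[:5])
        with pytest.raises(ValidationError):
            pair_differences(m, d)


class TestSurrogates:
    def test_pure_noise_yields_no_surrogates_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            D = diff_matrix(rng.normal(size=(2000, 7)))
            hits += estimate_surrogates(D, seed=seed).q == 0
        assert hits >= 18

    def test_planted_batch_recovered(self):
        rng = np.random.default_rng(7)
        batch = np.array([1.0, 1, 1, -1, -1, -1, 0])
        X = rng.normal(0, 0.3, size=(2000, 7))
        X[: 1000] += 0.8 * batch  # half the probes carry the batch pattern
        out = estimate_surrogates(diff_matrix(X), seed=8)
        assert out.q >= 1
        r = np.corrcoef(out.loadings[:, 0], batch)[0, 1]
        assert abs(r) > 0.9
        # loadings orthonormal
        gram = out.loadings.T @ out.loadings
        np.testing.assert_allclose(gram, np.eye(out.q), atol=1e-10)

    def test_zero_permutations_rejected(self):
        D = diff_matrix(np.zeros((10, 7)))
        with pytest.raises(ValidationError):
            estimate_surrogates(D, n_perm=0)


class TestModeratedFit:
    def test_equal_variances_collapse_to_pooled_estimate(self):
        """When every probe has the same s^2 the prior df is infinite, the
        posterior variance is the common pooled value (the log-variance
        estimate carries the chi-square bias correction
        exp(log(d/2) - psi(d/2)), matching the reference implementation),
        and the moderated t is the ordinary paired t up to that single
        constant factor."""
        from scipy.special import digamma

        rng = np.random.default_rng(2)
        base = rng.normal(size=7)
        base = (base - base.mean()) / base.std(ddof=1)
        shifts = rng.normal(size=50)
        X = base[None, :] + shifts[:, None]  # every row: identical s^2 = 1
        prior, table = fit_moderated(diff_matrix(X))
        assert math.isinf(prior.d0)
        # posterior variance is one shared constant
        assert table["s_sq_post"].std() < 1e-12
        correction = math.exp(math.log(3.0) - digamma(3.0))  # d = 6
        assert prior.s0_sq == pytest.approx(correction, rel=1e-9)
        t_ref = stats.ttest_1samp(X, 0, axis=1).statistic
        np.testing.assert_allclose(
            table["t_mod"] * math.sqrt(correction), t_ref, rtol=1e-9
        )

    def test_no_moderation_equals_brute_force_paired_t(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(1000, 7)) * np.exp(rng.normal(size=(1000, 1)))
        _, table = fit_moderated(diff_matrix(X), d0_override=0)
        ref = stats.ttest_1samp(X, 0, axis=1)
        assert np.abs(table["t_mod"].to_numpy() - ref.statistic).max() < 1e-10
        assert np.abs(table["p"].to_numpy() - ref.pvalue).max() < 1e-10

    def test_hyperparameter_recovery_from_scaled_inv_chisq(self):
        """Variances drawn from s0^2 d0 / chi2_d0 with d0=4, s0^2=0.04."""
        d0s, s0s = [], []
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            sig2 = 4 * 0.04 / rng.chisquare(4, size=5000)
            X = rng.normal(size=(5000, 7)) * np.sqrt(sig2)[:, None]
            prior, _ = fit_moderated(diff_matrix(X))
            d0s.append(prior.d0)
            s0s.append(prior.s0_sq)
        assert abs(np.median(d0s) - 4) / 4 < 0.25
        assert abs(np.median(s0s) - 0.04) / 0.04 < 0.10

    def test_matches_limma_reference(self):
        """Frozen reference computed with R limma 3.58.1 (lmFit + eBayes)
        on this exact fixture."""
        rng = np.random.default_rng(20260921)
        sd = np.exp(rng.normal(-1.0, 0.5, size=60))
        X = rng.normal(0.1, 1.0, size=(60, 7)) * sd[:, None]
        prior, table = fit_moderated(diff_matrix(X))
        assert prior.d0 == pytest.approx(3.316309958, rel=1e-6)
        assert prior.s0_sq == pytest.approx(0.1125841308, rel=1e-6)
        np.testing.assert_allclose(
            table["t_mod"].to_numpy()[:5],
            [-2.059150821, 0.2974162794, -1.203566843, -0.434757933, -0.2682795192],
            rtol=1e-6,
        )
        np.testing.assert_allclose(
            table["p"].to_numpy()[:5],
            [0.068524033, 0.7726742291, 0.2584472001, 0.6736351396, 0.7943302738],
            rtol=1e-6,
        )

    def test_pair_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 7))
        _, a = fit_moderated(diff_matrix(X))
        _, b = fit_moderated(diff_matrix(X[:, ::-1]))
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-10)

    def test_limits_of_the_prior_df(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 7)) * np.exp(rng.normal(size=(300, 1)))
        prior, _ = fit_moderated(diff_matrix(X))
        _, inf_fit = fit_moderated(diff_matrix(X), d0_override=math.inf)
        s0 = prior.s0_sq
        expected = X.mean(axis=1) * math.sqrt(7) / math.sqrt(s0)
        np.testing.assert_allclose(inf_fit["t_mod"], expected, rtol=1e-10)
        _, zero_fit = fit_moderated(diff_matrix(X), d0_override=0)
        ref = stats.ttest_1samp(X, 0, axis=1).statistic
        np.testing.assert_allclose(zero_fit["t_mod"], ref, rtol=1e-10)

    def test_insufficient_replication_rejected(self):
        X = np.zeros((10, 1))
        with pytest.raises(ValidationError):
            fit_moderated(diff_matrix(X))

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for x in [0.01, 0.1, 1.0, 5.0]:
            y = _trigamma_inverse(x)
            assert polygamma(1, y) == pytest.approx(x, rel=1e-6)


class TestNullCalibration:
    def test_p_values_uniform_under_null(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20000, 7))
        _, table = fit_moderated(diff_matrix(X))
        assert stats.kstest(table["p"], "uniform").pvalue > 0.01


class TestAdjustBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),  # hand-computed step-up
            ([0.04], [0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_adjustments(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected)

    def test_empty_vector(self):
        assert adjust_bh([]).size == 0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(500)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adjust_bh(p), ref, rtol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        q = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDmps:
    def test_strict_threshold_boundary(self, design7):
        stats_table = pd.DataFrame(
            {"mean_diff_m": [1.0, 1.0], "s_sq": [1, 1], "s_sq_post": [1, 1],
             "t_mod": [3, 3], "p": [0.0049, 0.0050], "df_total": [6, 6]},
            index=pd.Index(["cg1", "cg2"], name="probe_id"),
        )
        beta = make_beta_matrix(
            np.full((2, 14), 0.5), probes=["cg1", "cg2"],
            samples=list(design7.sample_ids),
        )
        out = call_dmps(stats_table, beta, design7)
        assert bool(out.loc["cg1", "significant"])
        assert not bool(out.loc["cg2", "significant"])

    def test_delta_beta_sign_matches_m_sign_on_spikes(self, small_cohort):
        bm, manifest, design, truth = small_cohort
        from twinmeth import filter_probes, quantile_normalize

        filt, _ = filter_probes(bm, manifest)
        norm = quantile_normalize(filt)
        diffs = pair_differences(beta_to_m(norm), design)
        _, table = fit_moderated(diffs)
        out = call_dmps(table, norm, design, manifest=manifest)
        tested_spikes = out.index.intersection(truth.spiked.index)
        called_spikes = tested_spikes[out.loc[tested_spikes, "significant"]]
        assert len(called_spikes) > 0
        signs = np.sign(out.loc[called_spikes, "delta_beta"])
        np.testing.assert_array_equal(signs, truth.spiked.loc[called_spikes, "sign"])

    def test_invalid_threshold_rejected(self, design7):
        stats_table = pd.DataFrame(
            {"mean_diff_m": [0.0], "s_sq": [1], "s_sq_post": [1],
             "t_mod": [0], "p": [0.5], "df_total": [6]},
            index=pd.Index(["cg1"], name="probe_id"),
        )
        beta = make_beta_matrix(np.full((1, 14), 0.5), probes=["cg1"],
                                samples=list(design7.sample_ids))
        with pytest.raises(ValidationError):
            call_dmps(stats_table, beta, design7, p_threshold=1.5)
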