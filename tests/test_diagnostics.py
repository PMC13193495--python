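"""Convergence diagnostics: oracle equivalence with an independent reference
implementation, analytic sanity cases, and PPC calibration."""

import warnings

import numpy as np
import pytest

import scalemarks as sm
from scalemarks.diagnostics import diagnose

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from arviz.stats.diagnostics import _bfmi, _ess_bulk, _rhat_split


class TestSplitRhat:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 1000))
        assert sm.split_rhat(x) < 1.01

    def test_disjoint_chains_diverge(self):
        x = np.vstack([np.zeros(100), np.full(100, 10.0)])
        x += np.random.default_rng(1).normal(0, 0.1, x.shape)
        assert sm.split_rhat(x) > 2.0

    def test_zero_variance_is_undefined(self):
        assert np.isnan(sm.split_rhat(np.zeros((4, 100))))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = np.cumsum(rng.standard_normal((4, 200)), axis=1) * 0.1 + rng.standard_normal((4, 200))
            assert sm.split_rhat(x) == pytest.approx(_rhat_split(x), abs=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            sm.split_rhat(np.zeros((1, 100)))


class TestEssBulk:
    def test_iid_near_total(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 1000))
        assert sm.ess_bulk(x) == pytest.approx(4000, rel=0.15)

    def test_ar1_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(4)
        n, c = 5000, 4
        x = np.empty((c, n))
        for i in range(c):
            e = rng.standard_normal(n)
            x[i, 0] = e[0]
            for t in range(1, n):
                x[i, t] = rho * x[i, t - 1] + np.sqrt(1 - rho**2) * e[t]
        expected = c * n * (1 - rho) / (1 + rho)
        assert sm.ess_bulk(x) == pytest.approx(expected, rel=0.25)

    def test_estimator_cap(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.standard_normal((4, 500))
            assert sm.ess_bulk(x) < 2.2 * x.size

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = np.cumsum(rng.standard_normal((4, 300)), axis=1) * 0.05 + rng.standard_normal((4, 300))
            assert sm.ess_bulk(x) == pytest.approx(_ess_bulk(x), rel=1e-6)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(sm.ess_bulk(np.ones((4, 100))))


class TestDivergenceCount:
    def test_counting_and_additivity(self):
        flags = np.zeros((2, 50), dtype=bool)
        assert sm.divergence_count({"diverging": flags}) == 0
        flags[0, 3] = flags[0, 7] = flags[1, 11] = True
        assert sm.divergence_count({"diverging": flags}) == 3
        per_chain = [int(flags[c].sum()) for c in range(2)]
        assert sm.divergence_count({"diverging": flags}) == sum(per_chain)


class TestEbfmi:
    def test_iid_energy_near_two(self):
        rng = np.random.default_rng(7)
        e = rng.standard_normal((4, 20_000))
        np.testing.assert_allclose(sm.ebfmi(e), 2.0, rtol=0.1)

    def test_random_walk_energy_is_small(self):
        rng = np.random.default_rng(8)
        e = np.cumsum(rng.standard_normal((2, 5000)), axis=1)
        assert np.all(sm.ebfmi(e) < 0.1)

    def test_constant_energy_undefined(self):
        assert np.all(np.isnan(sm.ebfmi(np.ones((2, 100)))))

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(9)
        e = rng.standard_normal((4, 500)) + np.cumsum(rng.standard_normal((4, 500)), axis=1) * 0.1
        np.testing.assert_allclose(sm.ebfmi(e), _bfmi(e), atol=1e-12)


class TestPpc:
    def test_well_specified_fit_is_calibrated(self, small_fit):
        design, counts, post = small_fit
        rng = np.random.default_rng(10)
        p = sm.ppc_pvalue(post, design, counts, "mean", rng=rng)
        assert 0.05 < p < 0.95
        # The dispersion p-value is biased high at small sample sizes: posterior
        # uncertainty in the variance components makes replicates slightly more
        # dispersed than any single realization.  Only extreme values signal a
        # genuine misfit, so the band is wider than for the mean statistic.
        p_disp = sm.ppc_pvalue(post, design, counts, "dispersion", rng=rng)
        assert 0.005 < p_disp < 0.995

    def test_overdispersed_counts_flagged(self, small_fit):
        """Counts inflated fivefold in variance fail the dispersion check."""
        design, counts, post = small_fit
        rng = np.random.default_rng(11)
        lam = counts.mean()
        # negative-binomial with variance ~5x the mean
        r = lam / 4.0
        over = rng.negative_binomial(r, r / (r + lam), size=counts.shape)
        p = sm.ppc_pvalue(post, design, over, "dispersion", rng=rng)
        assert p < 0.05

    def test_stable_in_number_of_draws(self, small_fit):
        """Monte-Carlo error: halving the retained draws moves p only slightly."""
        design, counts, post = small_fit
        rng = np.random.default_rng(12)
        p_full = sm.ppc_pvalue(post, design, counts, "mean", rng=rng)
        half = sm.PosteriorDraws(
            params={k: v[:, ::2] for k, v in post.params.items()},
            sampler_stats={k: v[:, ::2] for k, v in post.sampler_stats.items()},
            meta=post.meta,
        )
        p_half = sm.ppc_pvalue(half, design, counts, "mean", rng=rng)
        assert abs(p_full - p_half) < 0.06

    def test_unknown_statistic_rejected(self, small_fit):
        design, counts, post = small_fit
        with pytest.raises(ValueError):
            sm.ppc_pvalue(post, design, counts, "median")


class TestDiagnose:
    def test_report_structure_and_convergence_rule(self, small_fit):
        design, counts, post = small_fit
        report = diagnose(post, design, counts, ess_threshold=100.0,
                          ppc_rng=np.random.default_rng(13))
        assert set(report.rhat) == set(post.species_level_names())
        expected = (
            max(report.rhat.values()) <= 1.01
            and min(report.ess.values()) > 100.0
            and report.n_divergent == 0
        )
        assert report.converged == expected

    def test_converged_is_monotone_in_parameters(self, small_fit):
        """Injecting a non-mixing parameter can only break convergence."""
        design, counts, post = small_fit
        bad = sm.PosteriorDraws(
            params=dict(post.params), sampler_stats=post.sampler_stats, meta=dict(post.meta)
        )
        c, d = bad.params["alpha"].shape
        bad.params["beta[sex_M]"] = np.vstack(
            [np.zeros((1, d)), np.full((c - 1, d), 10.0)]
        ) + np.random.default_rng(14).normal(0, 0.01, (c, d))
        r_bad = diagnose(bad, ess_threshold=100.0)
        assert not r_bad.converged

    def test_strict_mode_monitors_offsets(self, small_fit):
        design, counts, post = small_fit
        report = diagnose(post, ess_threshold=1.0, strict=True)
        assert any(k.startswith("delta_alpha[") for k in report.rhat)
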