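"""Design-matrix coding, the ZIP pmf, the linear predictor, and the
hierarchical fit itself."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import scalemarks as sm
from scalemarks.design import DesignError, build_design, extract_counts
from scalemarks.model import FitError, ModelConfig, _Posterior, fit_model
from scalemarks.nuts import nuts_sample

from conftest import make_dataset


class TestBuildDesign:
    def test_reference_cell_is_all_zero(self):
        ds = make_dataset([("f1", "F", 22.0, "CM", 4.0, "good", 2),
                           ("f2", "F", 22.0, "CM", 6.0, "good", 2)])
        d = build_design(ds, centre=4.0)
        assert np.all(d.X[0] == 0.0)

    def test_male_AV_coding(self):
        ds = make_dataset([("f1", "M", 22.0, "AV", 4.0, "good", 2)])
        d = build_design(ds, centre=4.0)
        row = dict(zip(d.columns, d.X[0]))
        active = {k for k, v in row.items() if v != 0}
        assert active == {"sex_M", "H_A", "V_V", "HxV_AV"}

    def test_interaction_is_product_of_main_effects(self, small_bundle):
        readable = sm.filter_readable(small_bundle.dataset)
        d = build_design(readable, "auto")
        for h in ("A", "P"):
            for v in ("D", "V"):
                prod = d.column(f"H_{h}") * d.column(f"V_{v}")
                assert np.array_equal(prod, d.column(f"HxV_{h}{v}"))

    def test_specimen_index_dense(self, small_bundle):
        readable = sm.filter_readable(small_bundle.dataset)
        d = build_design(readable, "auto")
        assert len(set(d.specimen_index)) == len(readable.specimen_ids)
        assert d.specimen_index.max() == len(d.specimen_ids) - 1

    def test_auto_centre_is_mean_length(self, small_bundle):
        readable = sm.filter_readable(small_bundle.dataset)
        d = build_design(readable, "auto")
        lengths = [r.scale_length for r in readable]
        assert d.centre == pytest.approx(np.mean(lengths))
        assert d.column("length_c").mean() == pytest.approx(0.0, abs=1e-9)

    def test_mixed_species_rejected(self):
        recs = [
            sm.ScaleRecord("a", "curema", "LM", "F", 22.0, "CM", 4.0, status="good", marks=1),
            sm.ScaleRecord("b", "cephalus", "LM", "F", 25.0, "CM", 4.0, status="good", marks=1),
        ]
        with pytest.raises(DesignError):
            build_design(sm.ScaleDataset(recs), "auto")

    def test_unfiltered_dataset_rejected(self):
        ds = make_dataset([("f1", "F", 22.0, "CM", 4.0, "damaged", None),
                           ("f1", "F", 22.0, "CM", 4.0, "good", 1)])
        with pytest.raises(DesignError):
            build_design(ds, "auto")


class TestZipLogpmf:
    def test_poisson_limit_exact(self):
        for lam in (0.5, 1.0, 4.0, 10.0):
            y = np.arange(51)
            ours = sm.zip_logpmf(y, lam, 0.0)
            ref = stats.poisson.logpmf(y, lam)
            np.testing.assert_allclose(ours, ref, atol=1e-12, rtol=0)

    def test_known_values(self):
        assert sm.zip_logpmf(0, 1.0, 0.0) == pytest.approx(-1.0, abs=1e-12)
        assert sm.zip_logpmf(2, 2.0, 0.0) == pytest.approx(math.log(2) - 2, abs=1e-12)
        assert sm.zip_logpmf(0, 1.0, 0.5) == pytest.approx(
            math.log(0.5 + 0.5 * math.exp(-1)), abs=1e-12
        )

    @pytest.mark.parametrize("lam", [0.5, 4.0, 20.0])
    @pytest.mark.parametrize("pi", [0.0, 0.2, 0.7])
    def test_normalization(self, lam, pi):
        total = np.exp(sm.zip_logpmf(np.arange(201), lam, pi)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sm.zip_logpmf(1, -1.0, 0.0)
        with pytest.raises(ValueError):
            sm.zip_logpmf(1, 1.0, 1.0)


class TestLinearPredictor:
    def test_reference_cell(self):
        assert sm.linear_predictor(math.log(4), {}, {}) == pytest.approx(4.0)

    def test_single_effect(self):
        lam = sm.linear_predictor(0.0, {"sex_M": math.log(1.07)}, {"sex_M": 1.0})
        assert lam == pytest.approx(1.07)

    def test_positivity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lam = sm.linear_predictor(
                float(rng.normal()), {"x": float(rng.normal())}, {"x": float(rng.normal())}
            )
            assert lam > 0


class TestFitModel:
    def test_intercept_only_matches_conjugate_oracle(self):
        """Flat design: posterior of exp(alpha) vs Gamma-Poisson closed form."""
        rng = np.random.default_rng(6)
        n = 400
        y = rng.poisson(4.0, n)
        rows = []
        # two individuals, no covariate variation, tiny hierarchy
        for i, yi in enumerate(y):
            rows.append((f"f{i % 2}", "F", 22.0, "CM", 4.0, "good", int(yi)))
        ds = make_dataset(rows)
        design = build_design(ds, centre=4.0)
        counts = extract_counts(ds)
        cfg = ModelConfig(chains=2, tune=400, draws=400, seed=3, max_retries=0,
                          ess_threshold=50.0)
        post = fit_model(design, counts, cfg)
        lam_draws = np.exp(post.params["alpha"].reshape(-1))
        assert abs(lam_draws.mean() - y.mean()) < 2 * lam_draws.std() + 0.05

    def test_non_centred_identity(self, small_fit):
        _, _, post = small_fit
        lhs = post.params["alpha_i"]
        rhs = (
            post.params["alpha"][:, :, None]
            + post.params["delta_alpha"] * post.params["sigma_alpha"][:, :, None]
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12, rtol=0)

    def test_seeded_determinism(self):
        truth = sm.species_preset("curema", n_individuals=6)
        b = sm.simulate_dataset(truth, seed=4)
        readable = sm.filter_readable(b.dataset)
        design = build_design(readable, "auto")
        counts = extract_counts(readable)
        cfg = ModelConfig(chains=2, tune=100, draws=60, seed=9, max_retries=0,
                          ess_threshold=1.0)
        p1 = fit_model(design, counts, cfg)
        p2 = fit_model(design, counts, cfg)
        np.testing.assert_array_equal(p1.params["alpha"], p2.params["alpha"])
        np.testing.assert_array_equal(p1.params["beta_i"], p2.params["beta_i"])

    def test_counts_mismatch_raises(self, small_bundle):
        readable = sm.filter_readable(small_bundle.dataset)
        design = build_design(readable, "auto")
        with pytest.raises(FitError):
            fit_model(design, [1, 2, 3], ModelConfig(seed=0))

    def test_prior_recovery_without_data(self):
        """With no observations the posterior for alpha is its prior."""
        from scalemarks.simulate import DESIGN_COLUMNS

        design = sm.DesignMatrix(
            X=np.zeros((0, 10)),
            columns=DESIGN_COLUMNS,
            specimen_index=np.zeros(0, dtype=int),
            specimen_ids=["a", "b"],
            centre=0.0,
            species="curema",
        )
        cfg = ModelConfig(chains=2, tune=500, draws=2000, seed=12, max_retries=0,
                          ess_threshold=1.0)
        post = fit_model(design, np.zeros(0, dtype=int), cfg)
        a = post.params["alpha"].reshape(-1)
        assert abs(a.mean()) < 1.5
        assert 8.0 < a.std() < 12.0

    def test_zip_fit_recovers_inflation(self):
        """ZIP likelihood: posterior pi covers a substantial true pi."""
        truth = sm.species_preset("curema", n_individuals=40, pi=0.25)
        b = sm.simulate_dataset(truth, seed=14)
        readable = sm.filter_readable(b.dataset)
        design = build_design(readable, "auto")
        counts = extract_counts(readable)
        cfg = ModelConfig(likelihood="zip", chains=2, tune=400, draws=300,
                          seed=15, max_retries=0, ess_threshold=20.0)
        post = fit_model(design, counts, cfg)
        pi_draws = post.params["pi"].reshape(-1)
        lo, hi = sm.hdi(pi_draws, 0.95)
        assert lo <= 0.25 <= hi
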