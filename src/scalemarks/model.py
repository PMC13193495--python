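"""Non-centred hierarchical Bayesian Poisson / zero-inflated-Poisson model
for scale mark counts, one model per species.

Model. For scale j of individual i with covariate row x_j:

    alpha        ~ Normal(0, 10)            species-level intercept (log scale)
    sigma_alpha  ~ HalfCauchy(5)            between-individual intercept scale
    beta_f       ~ Normal(0, 10)            species-level effect of factor f
    sigma_beta_f ~ HalfCauchy(5)            between-individual slope scale
                                            (factors varying within individuals)
    dalpha_i     ~ Normal(0, 1)             non-centred intercept offset
    alpha_i      = alpha + dalpha_i * sigma_alpha
    dbeta_{i,f}  ~ Normal(0, 1)             non-centred slope offset
    beta_{i,f}   = beta_f + dbeta_{i,f} * sigma_beta_f
    lambda_j     = exp(alpha_i + x_j . beta_i)
    y_j          ~ Poisson(lambda_j)  or  ZIPoisson(pi, lambda_j)
    pi           ~ Beta(1, 1)               (zero-inflation weight, ZIP only)

The non-centred parameterization keeps the individual offsets standard-normal
a priori, which removes the hierarchical funnel between the shared deviation
scales and the individual effects; the sampler sees only unconstrained
coordinates (log-deviations, logit-pi). Gradients are computed analytically,
so a posterior evaluation costs one pass over the observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .design import DesignMatrix
from .nuts import nuts_sample

DEFAULT_RANDOM_SLOPES = tuple(
    c
    for c in (
        "length_c",
        "H_A",
        "H_P",
        "V_D",
        "V_V",
        "HxV_AD",
        "HxV_AV",
        "HxV_PD",
        "HxV_PV",
    )
)


class FitError(RuntimeError):
    """The sampler could not be run on the supplied inputs."""


# --- elementary model pieces ------------------------------------------------


def zip_logpmf(y, lam, pi):
    """Log pmf of the zero-inflated Poisson mixture.

    y = 0 -> log(pi + (1-pi) e^(-lam)); y > 0 -> log(1-pi) + Poisson log-pmf.
    With pi = 0 this reduces exactly to the Poisson log-pmf. Vectorized over
    any broadcastable combination of arguments.
    """
    y = np.asarray(y)
    lam = np.asarray(lam, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    if np.any(pi < 0) or np.any(pi >= 1):
        raise ValueError("pi must lie in [0, 1)")
    pois = y * np.log(lam) - lam - gammaln(y + 1.0)
    with np.errstate(divide="ignore"):
        zero = np.log(pi + (1.0 - pi) * np.exp(-lam))
        nonzero = np.log1p(-pi) + pois
    out = np.where(y == 0, zero, nonzero)
    return out if out.ndim else float(out)


def linear_predictor(alpha_i: float, beta_i: dict, x: dict) -> float:
    """Expected count exp(alpha_i + x . beta_i), evaluated in log space."""
    eta = alpha_i + sum(v * beta_i[f] for f, v in x.items() if v != 0)
    return math.exp(eta)


# --- configuration and results ----------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Sampler and prior settings; defaults mirror the model statement above."""

    likelihood: str = "poisson"  # "poisson" | "zip"
    prior_intercept_sd: float = 10.0
    prior_slope_sd: float = 10.0
    prior_shrinkage_scale: float = 5.0  # HalfCauchy scale for sigma terms
    pi_prior: tuple[float, float] = (1.0, 1.0)
    chains: int = 4
    tune: int = 2000
    draws: int = 1000
    target_accept: float = 0.9
    seed: int = 0
    max_retries: int = 1
    max_treedepth: int = 10
    ess_threshold: float = 2000.0
    random_slope_factors: tuple[str, ...] = DEFAULT_RANDOM_SLOPES

    def __post_init__(self) -> None:
        if self.likelihood not in ("poisson", "zip"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.chains < 2:
            raise ValueError("need at least two chains")
        for name in ("prior_intercept_sd", "prior_slope_sd", "prior_shrinkage_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorDraws:
    """Posterior samples indexed (chain, draw) plus sampler statistics.

    ``params`` maps names to arrays: scalars are (chains, draws); the
    individual offsets are (chains, draws, n_individuals) for the intercepts
    and (chains, draws, n_individuals, n_random_slopes) for the slopes, with
    derived alpha_i / beta_i reconstructed draw-by-draw from the non-centred
    identity.
    """

    params: dict[str, np.ndarray]
    sampler_stats: dict[str, np.ndarray]  # diverging, energy: (chains, draws)
    meta: dict

    @property
    def shape(self) -> tuple[int, int]:
        return self.params["alpha"].shape

    def species_level_names(self) -> list[str]:
        names = ["alpha", "sigma_alpha"]
        names += [f"beta[{c}]" for c in self.meta["columns"]]
        names += [f"sigma_beta[{f}]" for f in self.meta["random_slope_factors"]]
        if "pi" in self.params:
            names.append("pi")
        return names

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated, shape (chains*draws, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])


def draws_to_frame(draws: PosteriorDraws, full: bool = False) -> pd.DataFrame:
    """Long-format (parameter, chain, draw, value) table of the posterior."""
    rows = []
    names = list(draws.params) if full else draws.species_level_names()
    for name in names:
        arr = draws.params[name]
        if arr.ndim == 2:
            entries = {name: arr}
        elif arr.ndim == 3:
            entries = {f"{name}[{i}]": arr[:, :, i] for i in range(arr.shape[2])}
        else:
            fs = draws.meta["random_slope_factors"]
            entries = {
                f"{name}[{i},{f}]": arr[:, :, i, k]
                for i in range(arr.shape[2])
                for k, f in enumerate(fs)
            }
        for label, a in entries.items():
            c, d = a.shape
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": label,
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "value": a.reshape(-1),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# --- posterior density ------------------------------------------------------


class _Posterior:
    """Unconstrained log posterior and gradient for the hierarchical model.

    Parameter vector layout:
    [alpha, log sigma_alpha, beta (P), log sigma_beta (K),
     dalpha (I), dbeta (I*K, row-major), (logit pi if ZIP)]
    """

    def __init__(self, design: DesignMatrix, counts: np.ndarray, config: ModelConfig):
        # rows sorted by individual so per-individual sums are reduceat slices
        order = np.argsort(design.specimen_index, kind="stable")
        self.X = np.ascontiguousarray(design.X[order])
        self.idx = np.ascontiguousarray(design.specimen_index[order])
        self.y = np.ascontiguousarray(np.asarray(counts, dtype=float)[order])
        self.config = config
        self.columns = design.columns
        self.rs = tuple(f for f in config.random_slope_factors if f in design.columns)
        self.rs_cols = np.array([design.columns.index(f) for f in self.rs], dtype=int)
        self.X_rs = np.ascontiguousarray(self.X[:, self.rs_cols])
        self.P = self.X.shape[1]
        self.K = len(self.rs)
        self.I = design.n_individuals
        if self.y.size:
            present = np.zeros(self.I, dtype=bool)
            present[self.idx] = True
            if not present.all():
                raise FitError("every individual must contribute at least one row")
            self.starts = np.searchsorted(self.idx, np.arange(self.I))
        else:
            self.starts = np.zeros(0, dtype=int)
        self.zip = config.likelihood == "zip"
        self.dim = 2 + self.P + self.K + self.I + self.I * self.K + (1 if self.zip else 0)
        self.loggamma_y = float(np.sum(gammaln(self.y + 1.0)))
        self.y_is_zero = self.y == 0

    def unpack(self, q: np.ndarray):
        P, K, I = self.P, self.K, self.I
        o = 0
        alpha = q[o]; o += 1
        ls_a = q[o]; o += 1
        beta = q[o:o + P]; o += P
        ls_b = q[o:o + K]; o += K
        da = q[o:o + I]; o += I
        db = q[o:o + I * K].reshape(I, K); o += I * K
        t_pi = q[o] if self.zip else None
        return alpha, ls_a, beta, ls_b, da, db, t_pi

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        q = 0.1 * rng.uniform(-1, 1, self.dim)
        ybar = self.y.mean() if self.y.size else 1.0
        q[0] = math.log(max(ybar, 0.1) + 1e-3) + 0.05 * rng.uniform(-1, 1)
        q[1] = math.log(0.3)
        if self.K:
            q[2 + self.P:2 + self.P + self.K] = math.log(0.1)
        return q

    def eta(self, alpha, sa, beta, sb, da, db):
        e = alpha + sa * da[self.idx] + self.X @ beta
        if self.K:
            e = e + (self.X_rs * db[self.idx, :]) @ sb
        return e

    def __call__(self, q: np.ndarray):
        cfg = self.config
        alpha, ls_a, beta, ls_b, da, db, t_pi = self.unpack(q)
        sa = math.exp(ls_a)
        sb = np.exp(ls_b)
        if not np.isfinite(sa) or not np.all(np.isfinite(sb)):
            return -np.inf, np.zeros_like(q)
        eta = self.eta(alpha, sa, beta, sb, da, db)
        if eta.size and np.max(eta) > 500:
            return -np.inf, np.zeros_like(q)
        lam = np.exp(eta)

        grad = np.zeros_like(q)
        if self.zip:
            pi = expit(t_pi)
            em = np.exp(-lam)
            d0 = pi + (1.0 - pi) * em
            z = self.y_is_zero
            ll = float(
                np.sum(np.log(d0[z]))
                + np.sum(math.log1p(-pi) + self.y[~z] * eta[~z] - lam[~z])
            ) - float(np.sum(gammaln(self.y[~z] + 1.0)))
            w = np.empty_like(lam)
            w[~z] = self.y[~z] - lam[~z]
            w[z] = -lam[z] * (1.0 - pi) * em[z] / d0[z]
            dl_dpi = float(np.sum((1.0 - em[z]) / d0[z])) - np.count_nonzero(~z) / (1.0 - pi)
            a_pi, b_pi = cfg.pi_prior
            # Beta(a,b) prior on pi, evaluated in logit space
            ll += (a_pi - 1) * math.log(pi) + (b_pi - 1) * math.log1p(-pi)
            ll += math.log(pi) + math.log1p(-pi)  # Jacobian of logit
            dll_dt = (dl_dpi + (a_pi - 1) / pi - (b_pi - 1) / (1 - pi)) * pi * (1 - pi)
            dll_dt += 1.0 - 2.0 * pi
            grad[-1] = dll_dt
        else:
            ll = float(np.sum(self.y * eta - lam)) - self.loggamma_y
            w = self.y - lam

        # priors
        s_int = cfg.prior_intercept_sd
        s_slope = cfg.prior_slope_sd
        c_half = cfg.prior_shrinkage_scale
        ll += -0.5 * (alpha / s_int) ** 2
        ll += -0.5 * float(np.sum((beta / s_slope) ** 2))
        ll += -math.log1p((sa / c_half) ** 2) + ls_a
        ll += float(np.sum(-np.log1p((sb / c_half) ** 2) + ls_b))
        ll += -0.5 * float(np.sum(da * da)) - 0.5 * float(np.sum(db * db))
        if not np.isfinite(ll):
            return -np.inf, np.zeros_like(q)

        P, K, I = self.P, self.K, self.I
        grad[0] = float(np.sum(w)) - alpha / s_int**2
        if self.y.size:
            agg_w = np.add.reduceat(w, self.starts)
        else:
            agg_w = np.zeros(I)
        grad[1] = sa * float(np.dot(agg_w, da)) - 2 * sa**2 / (c_half**2 + sa**2) + 1.0
        grad[2:2 + P] = w @ self.X - beta / s_slope**2
        if K:
            if self.y.size:
                agg = np.add.reduceat(w[:, None] * self.X_rs, self.starts, axis=0)
            else:
                agg = np.zeros((I, K))
            grad[2 + P:2 + P + K] = (
                sb * np.einsum("ik,ik->k", agg, db)
                - 2 * sb**2 / (c_half**2 + sb**2)
                + 1.0
            )
            grad[2 + P + K + I:2 + P + K + I + I * K] = (agg * sb - db).reshape(-1)
        grad[2 + P + K:2 + P + K + I] = sa * agg_w - da
        return ll, grad


# --- fitting ----------------------------------------------------------------


def fit_model(
    design: DesignMatrix, counts: Sequence[int], config: ModelConfig
) -> PosteriorDraws:
    """Sample the posterior with NUTS under the non-centred parameterization.

    Runs ``config.chains`` chains sequentially (each with its own child seed);
    if the convergence criteria (max split R-hat <= 1.01, total bulk ESS above
    the configured threshold for species-level parameters, zero divergences)
    fail and retries remain, the tuning and sampling lengths are doubled once
    and the model refit.
    """
    from .diagnostics import ess_bulk, split_rhat  # deferred: avoids cycle

    counts = np.asarray(counts)
    if counts.ndim != 1 or len(counts) != design.n_rows:
        raise FitError(
            f"counts length {len(counts)} does not match design rows {design.n_rows}"
        )
    if np.any(counts < 0):
        raise FitError("counts must be non-negative")
    if design.n_individuals < 2:
        raise FitError("need at least two individuals for a hierarchical fit")

    tune, draws_n = config.tune, config.draws
    attempt = 0
    while True:
        post = _sample_once(design, counts, config, tune, draws_n)
        names = post.species_level_names()
        rhats = np.array([split_rhat(post.params[n]) for n in names])
        esss = np.array([ess_bulk(post.params[n]) for n in names])
        ndiv = int(post.sampler_stats["diverging"].sum())
        ok = (
            np.all(np.isfinite(rhats))
            and float(np.nanmax(rhats)) <= 1.01
            and float(np.nanmin(esss)) > config.ess_threshold
            and ndiv == 0
        )
        post.meta["converged"] = bool(ok)
        post.meta["attempts"] = attempt + 1
        if ok or attempt >= config.max_retries:
            return post
        attempt += 1
        tune, draws_n = tune * 2, draws_n * 2


def _sample_once(design, counts, config, tune, draws_n) -> PosteriorDraws:
    posterior = _Posterior(design, counts, config)
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains)
    C, D = config.chains, draws_n
    raw = np.empty((C, D, posterior.dim))
    div = np.empty((C, D), dtype=bool)
    energy = np.empty((C, D))
    for c in range(C):
        rng = np.random.default_rng(chain_seeds[c])
        init = posterior.initial_point(rng)
        lp0, _ = posterior(init)
        if not np.isfinite(lp0):
            a, ls_a, beta, ls_b, *_ = posterior.unpack(init)
            raise FitError(
                "non-finite likelihood at initialization: "
                f"alpha={a:.3f}, log sigma_alpha={ls_a:.3f}"
            )
        res = nuts_sample(
            posterior,
            init,
            n_tune=tune,
            n_draws=D,
            rng=rng,
            target_accept=config.target_accept,
            max_treedepth=config.max_treedepth,
        )
        raw[c] = res.draws
        div[c] = res.divergent
        energy[c] = res.energy

    P, K, I = posterior.P, posterior.K, posterior.I
    params: dict[str, np.ndarray] = {}
    o = 0
    params["alpha"] = raw[:, :, o]; o += 1
    params["sigma_alpha"] = np.exp(raw[:, :, o]); o += 1
    for j, col in enumerate(design.columns):
        params[f"beta[{col}]"] = raw[:, :, o + j]
    o += P
    for k, f in enumerate(posterior.rs):
        params[f"sigma_beta[{f}]"] = np.exp(raw[:, :, o + k])
    o += K
    params["delta_alpha"] = raw[:, :, o:o + I]; o += I
    params["delta_beta"] = raw[:, :, o:o + I * K].reshape(C, D, I, K); o += I * K
    if posterior.zip:
        params["pi"] = expit(raw[:, :, o])
    params["alpha_i"] = (
        params["alpha"][:, :, None]
        + params["delta_alpha"] * params["sigma_alpha"][:, :, None]
    )
    if K:
        beta_rs = np.stack([params[f"beta[{f}]"] for f in posterior.rs], axis=-1)
        sigma_rs = np.stack(
            [params[f"sigma_beta[{f}]"] for f in posterior.rs], axis=-1
        )
        params["beta_i"] = (
            beta_rs[:, :, None, :] + params["delta_beta"] * sigma_rs[:, :, None, :]
        )
    else:
        params["beta_i"] = np.zeros((C, D, I, 0))

    return PosteriorDraws(
        params=params,
        sampler_stats={"diverging": div, "energy": energy},
        meta={
            "columns": list(design.columns),
            "random_slope_factors": list(posterior.rs),
            "specimen_ids": list(design.specimen_ids),
            "centre": design.centre,
            "species": design.species,
            "likelihood": config.likelihood,
            "seed": config.seed,
            "tune": tune,
            "draws": draws_n,
            "chains": C,
            "target_accept": config.target_accept,
        },
    )
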