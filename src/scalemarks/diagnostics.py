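"""Convergence and goodness-of-fit diagnostics for posterior draws.

Implements split R-hat (half-chain Gelman-Rubin), rank-normalized bulk
effective sample size with Geyer's initial-monotone autocorrelation
truncation, divergence counting, per-chain E-BFMI, and posterior-predictive
Bayesian p-values. A fit is declared converged when max split R-hat <= 1.01,
the minimum total bulk ESS over monitored parameters exceeds the threshold,
and no post-warmup transition diverged.

Zero-variance inputs yield NaN ("undefined") rather than a spuriously perfect
value; an undefined diagnostic never counts as converged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Optional

import numpy as np
from scipy import stats
from scipy.fft import next_fast_len

if TYPE_CHECKING:  # pragma: no cover
    from .design import DesignMatrix
    from .model import PosteriorDraws


def _validate_chains(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (chain, draw) array")
    if x.shape[0] < 2:
        raise ValueError("need at least two chains")
    if x.shape[1] < 4:
        raise ValueError("need at least four draws per chain")
    return x


def _split_chains(x: np.ndarray) -> np.ndarray:
    half = x.shape[1] // 2
    return np.vstack([x[:, :half], x[:, -half:]])


def split_rhat(chains: np.ndarray) -> float:
    """Split potential scale reduction factor.

    Each chain is halved, and the usual between/within variance ratio is
    computed on the half-chains: sqrt((N-1)/N + B/(N W)). Returns NaN when the
    draws have no variance (the statistic is undefined, not 1).
    """
    x = _split_chains(_validate_chains(chains))
    n = x.shape[1]
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    if w == 0.0 or not np.isfinite(w):
        return float("nan")
    b = n * float(np.var(np.mean(x, axis=1), ddof=1))
    return float(np.sqrt((n - 1) / n + b / (n * w)))


def _z_scale(x: np.ndarray) -> np.ndarray:
    """Rank-normalize: midranks over the whole array -> normal quantiles."""
    ranks = stats.rankdata(x, method="average").reshape(x.shape)
    size = x.size
    return stats.norm.ppf((ranks - 0.375) / (size - 0.75 + 1))


def _autocov(x: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance at every lag via FFT (biased, /n)."""
    n = x.shape[1]
    m = next_fast_len(2 * n)
    xc = x - x.mean(axis=1, keepdims=True)
    f = np.fft.rfft(xc, n=m, axis=1)
    f *= np.conjugate(f)
    return np.fft.irfft(f, n=m, axis=1)[:, :n] / n


def ess_bulk(chains: np.ndarray) -> float:
    """Rank-normalized split-chain bulk effective sample size.

    Paired autocorrelations are truncated by Geyer's initial positive and
    monotone sequences; the total (across chains) number of effectively
    independent draws is returned. NaN for zero-variance input.
    """
    x = _validate_chains(chains)
    if float(np.max(x) - np.min(x)) == 0.0:
        return float("nan")
    z = _z_scale(_split_chains(x))
    n_chain, n_draw = z.shape
    acov = _autocov(z)
    mean_var = float(np.mean(acov[:, 0])) * n_draw / (n_draw - 1.0)
    var_plus = mean_var * (n_draw - 1.0) / n_draw
    if n_chain > 1:
        var_plus += float(np.var(z.mean(axis=1), ddof=1))
    if var_plus == 0.0:
        return float("nan")

    rho = np.zeros(n_draw)
    rho[0] = 1.0
    rho_even = 1.0
    rho_odd = 1.0 - (mean_var - float(np.mean(acov[:, 1]))) / var_plus
    rho[1] = rho_odd
    t = 1
    while t < (n_draw - 3) and (rho_even + rho_odd) > 0.0:
        rho_even = 1.0 - (mean_var - float(np.mean(acov[:, t + 1]))) / var_plus
        rho_odd = 1.0 - (mean_var - float(np.mean(acov[:, t + 2]))) / var_plus
        if (rho_even + rho_odd) >= 0:
            rho[t + 1] = rho_even
            rho[t + 2] = rho_odd
        t += 2
    max_t = t - 2
    if rho_even > 0:
        rho[max_t + 1] = rho_even
    # enforce monotone decrease of the paired sums
    t = 1
    while t <= max_t - 2:
        if (rho[t + 1] + rho[t + 2]) > (rho[t - 1] + rho[t]):
            rho[t + 1] = (rho[t - 1] + rho[t]) / 2.0
            rho[t + 2] = rho[t + 1]
        t += 2
    n_total = n_chain * n_draw
    tau = -1.0 + 2.0 * float(np.sum(rho[: max_t + 1])) + float(np.sum(rho[max_t + 1 : max_t + 2]))
    tau = max(tau, 1.0 / np.log10(n_total))
    return float(n_total / tau)


def divergence_count(sampler_stats: Mapping[str, np.ndarray]) -> int:
    """Total divergent transitions across chains (post-warmup draws only)."""
    return int(np.asarray(sampler_stats["diverging"]).sum())


def ebfmi(energy: np.ndarray) -> np.ndarray:
    """Per-chain energy-based Bayesian fraction of missing information.

    mean squared successive energy difference divided by the energy variance;
    values well below 1 flag poor exploration of the energy marginal. NaN for
    a chain with constant energy.
    """
    e = np.atleast_2d(np.asarray(energy, dtype=float))
    if e.shape[1] < 2:
        raise ValueError("need at least two draws per chain")
    num = np.square(np.diff(e, axis=1)).mean(axis=1)
    den = np.var(e, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


# --- posterior predictive checks ---------------------------------------------


def _statistic(counts: np.ndarray, which: str, axis=None):
    if which == "mean":
        return counts.mean(axis=axis)
    if which == "dispersion":
        m = counts.mean(axis=axis)
        v = counts.var(axis=axis, ddof=1)
        return v / m
    raise ValueError(f"unknown statistic {which!r}")


def posterior_rates(draws: "PosteriorDraws", design: "DesignMatrix") -> np.ndarray:
    """Expected count per (retained draw, observation) at the individual level."""
    alpha_i = draws.stacked("alpha_i")  # (S, I)
    rs = draws.meta["random_slope_factors"]
    idx = design.specimen_index
    eta = alpha_i[:, idx]
    if draws.meta["columns"]:
        beta_full = np.stack(
            [draws.stacked(f"beta[{c}]") for c in draws.meta["columns"]], axis=-1
        )  # (S, P)
        eta = eta + beta_full @ design.X.T
    if rs:
        rs_cols = [design.columns.index(f) for f in rs]
        beta_i = draws.stacked("beta_i")  # (S, I, K)
        for k, (f, col) in enumerate(zip(rs, rs_cols)):
            dev = beta_i[:, :, k] - draws.stacked(f"beta[{f}]")[:, None]  # (S, I)
            eta += design.X[:, col][None, :] * dev[:, idx]
    return np.exp(eta)


def ppc_pvalue(
    draws: "PosteriorDraws",
    design: "DesignMatrix",
    counts,
    statistic: str = "mean",
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Bayesian p-value: P(T(replicate) >= T(observed)) over posterior draws.

    For every retained draw, replicate counts are simulated from the
    likelihood at that draw's individual-level parameters, and the test
    statistic (mean, or variance/mean dispersion ratio) compared with the
    observed one. Well-calibrated fits give values near 0.5.
    """
    counts = np.asarray(counts)
    if rng is None:
        rng = np.random.default_rng(draws.meta.get("seed", 0))
    lam = posterior_rates(draws, design)  # (S, n)
    reps = rng.poisson(lam)
    if "pi" in draws.params:
        pi = draws.stacked("pi")[:, None]
        reps = np.where(rng.random(lam.shape) < pi, 0, reps)
    t_obs = _statistic(counts, statistic)
    t_rep = _statistic(reps, statistic, axis=1)
    return float(np.mean(t_rep >= t_obs))


# --- aggregate report ---------------------------------------------------------


@dataclass
class DiagnosticsReport:
    """Convergence summary over monitored parameters."""

    rhat: dict[str, float]
    ess: dict[str, float]
    n_divergent: int
    ebfmi: np.ndarray
    ppc_pvalues: dict[str, float]
    ess_threshold: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess": self.ess,
            "n_divergent": self.n_divergent,
            "ebfmi": [float(v) for v in self.ebfmi],
            "ppc_pvalues": self.ppc_pvalues,
            "ess_threshold": self.ess_threshold,
            "converged": self.converged,
        }


def diagnose(
    draws: "PosteriorDraws",
    design: Optional["DesignMatrix"] = None,
    counts=None,
    ess_threshold: float = 2000.0,
    strict: bool = False,
    ppc_rng: Optional[np.random.Generator] = None,
) -> DiagnosticsReport:
    """Compute the full diagnostics report for a fit.

    Monitored parameters are the species-level ones (intercept, deviation
    scales, factor effects, and pi when present); ``strict`` additionally
    monitors every individual offset.
    """
    names = draws.species_level_names()
    arrays: dict[str, np.ndarray] = {n: draws.params[n] for n in names}
    if strict:
        for base in ("delta_alpha", "alpha_i"):
            arr = draws.params[base]
            for i in range(arr.shape[2]):
                arrays[f"{base}[{i}]"] = arr[:, :, i]
        db = draws.params["delta_beta"]
        bi = draws.params["beta_i"]
        for i in range(db.shape[2]):
            for k, f in enumerate(draws.meta["random_slope_factors"]):
                arrays[f"delta_beta[{i},{f}]"] = db[:, :, i, k]
                arrays[f"beta_i[{i},{f}]"] = bi[:, :, i, k]
    rhat = {n: split_rhat(a) for n, a in arrays.items()}
    ess = {n: ess_bulk(a) for n, a in arrays.items()}
    ndiv = divergence_count(draws.sampler_stats)
    bfmi = ebfmi(draws.sampler_stats["energy"])
    ppc: dict[str, float] = {}
    if design is not None and counts is not None:
        for statname in ("mean", "dispersion"):
            p = ppc_pvalue(draws, design, counts, statname, rng=ppc_rng)
            ppc[statname] = p
            ppc[f"{statname}_complement"] = 1.0 - p
    rvals = np.array(list(rhat.values()))
    evals = np.array(list(ess.values()))
    converged = bool(
        np.all(np.isfinite(rvals))
        and np.all(np.isfinite(evals))
        and rvals.max() <= 1.01
        and evals.min() > ess_threshold
        and ndiv == 0
    )
    return DiagnosticsReport(
        rhat=rhat,
        ess=ess,
        n_divergent=ndiv,
        ebfmi=bfmi,
        ppc_pvalues=ppc,
        ess_threshold=ess_threshold,
        converged=converged,
    )
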