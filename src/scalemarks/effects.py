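"""Posterior summaries on the multiplicative (effect) scale.

After inverting the exponential link, each factor's effect is a multiplier on
the expected mark count: 1 means no effect. Summaries are the posterior mean,
the 95% highest-density interval, and the direction probability — the larger
of P(effect > 1) and P(effect < 1). The HDI uses the deterministic
sorted-window estimator (shortest contiguous window holding ceil(prob*n)
sorted draws), not a kernel-density method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .records import HORIZONTAL, VERTICAL
from .simulate import DESIGN_COLUMNS, SyntheticTruth


def hdi(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window of the sorted sample containing
    ceil(prob * n) draws; ties broken by the earliest start."""
    if not 0 < prob < 1:
        raise ValueError("prob must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < math.ceil(1.0 / (1.0 - prob)):
        raise ValueError(f"need at least {math.ceil(1.0 / (1.0 - prob))} samples")
    m = math.ceil(prob * n)
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))  # argmin returns the first minimizer
    return float(x[j]), float(x[j + m - 1])


def prob_direction(samples, reference: float = 1.0) -> float:
    """max(P(sample > reference), P(sample < reference)); draws exactly at
    the reference count toward neither side."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    above = float(np.mean(x > reference))
    below = float(np.mean(x < reference))
    return max(above, below)


@dataclass(frozen=True)
class EffectRow:
    mean_effect: float
    hdi_low: float
    hdi_high: float
    prob_direction: float


@dataclass
class EffectSummary:
    """Per-factor exp-scale summaries of the species-level effects."""

    factors: dict[str, EffectRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "factor": f,
                    "mean": r.mean_effect,
                    "hdi_low": r.hdi_low,
                    "hdi_high": r.hdi_high,
                    "prob_direction": r.prob_direction,
                }
                for f, r in self.factors.items()
            ]
        )


def effect_summary(draws, prob: float = 0.95) -> EffectSummary:
    """Exponentiate each species-level factor effect, then summarize.

    Exponentiation is monotone, so the HDI window on the effect scale is the
    image of a contiguous sorted window of the log-scale draws.
    """
    out: dict[str, EffectRow] = {}
    for col in draws.meta["columns"]:
        key = f"beta[{col}]"
        if key not in draws.params:
            raise KeyError(f"posterior lacks parameter {key}")
        eff = np.exp(draws.params[key].reshape(-1))
        low, high = hdi(eff, prob)
        out[col] = EffectRow(
            mean_effect=float(np.mean(eff)),
            hdi_low=low,
            hdi_high=high,
            prob_direction=prob_direction(eff, 1.0),
        )
    return EffectSummary(out)


@dataclass
class InteractionSurface:
    """Posterior expected count per (horizontal, vertical) body-area cell."""

    grid: dict[tuple[str, str], tuple[float, float, float]]  # mean, low, high

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"horizontal": h, "vertical": v, "mean": m, "hdi_low": lo, "hdi_high": hi}
                for (h, v), (m, lo, hi) in self.grid.items()
            ]
        )


def _cell_lograte(draws, h: str, v: str, sex: str) -> np.ndarray:
    eta = draws.stacked("alpha").copy()
    if sex == "M":
        eta = eta + draws.stacked("beta[sex_M]")
    if h in ("A", "P"):
        eta = eta + draws.stacked(f"beta[H_{h}]")
    if v in ("D", "V"):
        eta = eta + draws.stacked(f"beta[V_{v}]")
    if h in ("A", "P") and v in ("D", "V"):
        eta = eta + draws.stacked(f"beta[HxV_{h}{v}]")
    return eta


def interaction_surface(
    draws, sex: str = "F", p_male: Optional[float] = None, prob: float = 0.95
) -> InteractionSurface:
    """Expected mark count per body-area cell at species-level parameters.

    Conditions on mean scale length (centred length 0) and the given sex; no
    individual offsets enter, so this is the population-level surface.
    ``sex="marginal"`` averages the rate over the sex mix ``p_male``.
    """
    grid = {}
    for h in HORIZONTAL:
        for v in VERTICAL:
            if sex == "marginal":
                if p_male is None:
                    raise ValueError("marginal surface needs p_male")
                lam = (1 - p_male) * np.exp(_cell_lograte(draws, h, v, "F")) + (
                    p_male
                ) * np.exp(_cell_lograte(draws, h, v, "M"))
            else:
                lam = np.exp(_cell_lograte(draws, h, v, sex))
            low, high = hdi(lam, prob)
            grid[(h, v)] = (float(np.mean(lam)), low, high)
    return InteractionSurface(grid)


@dataclass
class RecoveryReport:
    """Did the HDIs capture the generative truth, factor by factor?"""

    rows: dict[str, dict]
    coverage_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"factor": f, **r} for f, r in self.rows.items()]
        )


def recovery_report(truth: SyntheticTruth, summary: EffectSummary) -> RecoveryReport:
    """Check each true exp-scale effect against its posterior HDI."""
    if set(summary.factors) != set(truth.beta):
        raise KeyError(
            f"factor mismatch: truth {sorted(truth.beta)} vs "
            f"summary {sorted(summary.factors)}"
        )
    rows = {}
    covered = []
    for f, row in summary.factors.items():
        true_eff = math.exp(truth.beta[f])
        ok = row.hdi_low <= true_eff <= row.hdi_high
        covered.append(ok)
        rows[f] = {
            "truth": true_eff,
            "posterior_mean": row.mean_effect,
            "hdi_low": row.hdi_low,
            "hdi_high": row.hdi_high,
            "covered": ok,
        }
    return RecoveryReport(rows=rows, coverage_fraction=float(np.mean(covered)))
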