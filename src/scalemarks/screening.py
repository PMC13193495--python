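"""Pre-model screening: damage/regeneration rates, the locality screen,
and the scale-length / standard-length correlation.

The locality screen asks whether sampling locality shifts mark counts; if it
does not, locality is dropped from the downstream model. Because scales are
repeated measures within a specimen, the default screening unit is the
per-individual mean mark count (a per-scale variant is available but
pseudo-replicates).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import AREAS, ScaleDataset


class DegenerateDataError(ValueError):
    """The data admit no test statistic (e.g. all values tied)."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding used only at presentation time."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class StatusTable:
    """Percentage of damaged-or-regenerated scales per (area, locality) cell.

    ``cells`` holds unrounded percentages; rounding to one decimal happens
    only when rendering. ``column_summary`` gives per-locality mean and sample
    SD (n-1 denominator) over the area percentages present in that locality.
    """

    cells: dict[tuple[str, str], float]
    column_summary: dict[str, tuple[float, float]]
    counts: dict[tuple[str, str], tuple[int, int]]

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        localities = sorted({loc for _, loc in self.cells})
        data = {}
        for loc in localities:
            col = []
            for area in AREAS:
                v = self.cells.get((area, loc))
                col.append(np.nan if v is None else (round_half_up(v) if rounded else v))
            data[loc] = col
        return pd.DataFrame(data, index=list(AREAS))


def status_percentage_table(dataset: ScaleDataset) -> StatusTable:
    """Tabulate the share of unusable (damaged or regenerated) scales.

    Cell(area, locality) = 100 * (#damaged + #regenerated) / #total among
    that cell's scales; cells with no scales are absent and excluded from the
    per-locality summaries.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    for rec in dataset:
        key = (rec.area, rec.locality)
        bad_total = counts.setdefault(key, [0, 0])
        bad_total[1] += 1
        if rec.status != "good":
            bad_total[0] += 1
    cells = {k: 100.0 * bad / total for k, (bad, total) in counts.items()}
    summary: dict[str, tuple[float, float]] = {}
    for loc in sorted({loc for _, loc in cells}):
        vals = np.array([v for (a, l), v in cells.items() if l == loc])
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        summary[loc] = (float(np.mean(vals)), sd)
    return StatusTable(
        cells=cells,
        column_summary=summary,
        counts={k: (bad, total) for k, (bad, total) in counts.items()},
    )


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal-Wallis H with its chi-square p-value."""

    H: float
    df: int
    p_value: float
    tie_correction: float


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> KWResult:
    """Rank-based k-sample location test with midranks and tie correction.

    H = [12 / (N(N+1)) * sum_j R_j^2 / n_j - 3(N+1)] / C with
    C = 1 - sum(t^3 - t) / (N^3 - N) over tie groups; the p-value is the
    upper tail of chi-square with k-1 degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be parallel 1-d sequences")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DegenerateDataError("need at least two groups")
    n_total = len(values)
    ranks = stats.rankdata(values)  # midranks
    h = 0.0
    for lab in labels:
        mask = groups == lab
        n_j = int(mask.sum())
        if n_j == 0:
            raise DegenerateDataError(f"group {lab!r} is empty")
        r_j = ranks[mask].sum()
        h += r_j**2 / n_j
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n_total**3 - n_total)
    if correction == 0.0:
        raise DegenerateDataError("all observations identical: H undefined")
    h /= correction
    df = len(labels) - 1
    return KWResult(
        H=float(h),
        df=df,
        p_value=float(stats.chi2.sf(h, df)),
        tie_correction=correction,
    )


def marks_by_locality(
    dataset: ScaleDataset, per_scale: bool = False
) -> tuple[list[float], list[str]]:
    """Arrange mark counts for the locality screen.

    Default unit: per-individual mean mark count over that individual's good
    scales (avoids pseudo-replication from repeated measures). ``per_scale``
    uses every good scale as an observation instead.
    """
    values: list[float] = []
    groups: list[str] = []
    if per_scale:
        for rec in dataset:
            if rec.status == "good":
                values.append(float(rec.marks))
                groups.append(rec.locality)
    else:
        per_ind: dict[str, list[int]] = {}
        loc_of: dict[str, str] = {}
        for rec in dataset:
            if rec.status == "good":
                per_ind.setdefault(rec.specimen_id, []).append(rec.marks)
                loc_of[rec.specimen_id] = rec.locality
        for sid, marks in per_ind.items():
            values.append(float(np.mean(marks)))
            groups.append(loc_of[sid])
    return values, groups


def length_correlation(dataset: ScaleDataset) -> float:
    """Pearson correlation between scale length and specimen standard length."""
    lsc = np.array([r.scale_length for r in dataset], dtype=float)
    sl = np.array([r.standard_length for r in dataset], dtype=float)
    if len(lsc) < 3:
        raise DegenerateDataError("need at least three records for a correlation")
    if np.std(lsc) == 0 or np.std(sl) == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    return float(np.corrcoef(lsc, sl)[0, 1])
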