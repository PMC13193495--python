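"""Covariate encoding for the hierarchical count model.

Dummy coding with reference cell (central, middle) — the recommended sampling
area — and sex reference female: columns sex_M, centred scale length, two
horizontal dummies (A, P), two vertical dummies (D, V), and the four
products. Each row maps back to its specimen through a dense specimen index
so individual-level effects can be attached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ScaleDataset
from .simulate import DESIGN_COLUMNS


class DesignError(ValueError):
    """The dataset cannot be encoded (mixed species, unreadable scales...)."""


@dataclass
class DesignMatrix:
    """Encoded covariates for good scales of a single species."""

    X: np.ndarray  # (n_rows, 10) float
    columns: tuple[str, ...]
    specimen_index: np.ndarray  # (n_rows,) int, dense 0..n_individuals-1
    specimen_ids: list[str]
    centre: float
    species: str

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.specimen_ids)

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]


def build_design(dataset: ScaleDataset, centre="auto") -> DesignMatrix:
    """Encode a good-scales single-species dataset into a design matrix.

    ``centre`` is the scale-length value subtracted before entering the
    length column ("auto" uses the dataset mean; centring only shifts the
    intercept, the per-unit slope is unchanged).
    """
    species = {r.species for r in dataset}
    if len(species) != 1:
        raise DesignError(f"mixed species in design input: {sorted(species)}")
    bad = [r for r in dataset if r.status != "good"]
    if bad:
        raise DesignError(
            f"{len(bad)} non-good scales present; run filter_readable first"
        )
    lengths = np.array([r.scale_length for r in dataset], dtype=float)
    c = float(np.mean(lengths)) if centre == "auto" else float(centre)

    ids: list[str] = []
    index_of: dict[str, int] = {}
    rows = np.zeros((len(dataset), len(DESIGN_COLUMNS)), dtype=float)
    spec_idx = np.zeros(len(dataset), dtype=np.int64)
    col = {name: j for j, name in enumerate(DESIGN_COLUMNS)}
    for i, rec in enumerate(dataset):
        if rec.specimen_id not in index_of:
            index_of[rec.specimen_id] = len(ids)
            ids.append(rec.specimen_id)
        spec_idx[i] = index_of[rec.specimen_id]
        rows[i, col["sex_M"]] = 1.0 if rec.sex == "M" else 0.0
        rows[i, col["length_c"]] = rec.scale_length - c
        h, v = rec.area[0], rec.area[1]
        if h in ("A", "P"):
            rows[i, col[f"H_{h}"]] = 1.0
        if v in ("D", "V"):
            rows[i, col[f"V_{v}"]] = 1.0
        if h in ("A", "P") and v in ("D", "V"):
            rows[i, col[f"HxV_{h}{v}"]] = 1.0

    return DesignMatrix(
        X=rows,
        columns=DESIGN_COLUMNS,
        specimen_index=spec_idx,
        specimen_ids=ids,
        centre=c,
        species=species.pop(),
    )


def extract_counts(dataset: ScaleDataset) -> np.ndarray:
    """Mark counts aligned with the rows :func:`build_design` produces."""
    return np.array([r.marks for r in dataset], dtype=np.int64)
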