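"""Synthetic scale-mark data with known ground truth.

The generator draws from the same generative model that is later fitted:
individual intercepts and slopes arise non-centred (standard-normal offsets
scaled by shared deviations around species-level means), the linear predictor
is exponentiated into a Poisson rate, and an optional zero-inflation weight
``pi`` replaces a draw with a structural zero. Around that core it emulates
the field study's structure: six Gulf-of-Mexico localities with
locality-specific standard-length distributions and sex ratios, nine body
areas sampled with 3-4 scales each, area-dependent damage/regeneration rates,
and scale length generated as a linear function of standard length with the
noise calibrated to a target Pearson correlation.

Everything is driven by a single seeded numpy Generator so a
(truth, seed) pair reproduces a bundle field-for-field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .records import AREAS, ScaleDataset, ScaleRecord

#: Design-matrix column names, in canonical order. Reference cell is a female
#: scale at area CM with scale length at the centring value.
DESIGN_COLUMNS = (
    "sex_M",
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

#: Factors that may carry individual-level offsets: everything that varies
#: within an individual. Sex is constant within a specimen, so a per-individual
#: sex slope would be confounded with the individual intercept.
WITHIN_INDIVIDUAL_FACTORS = tuple(c for c in DESIGN_COLUMNS if c != "sex_M")


class TruthConfigError(ValueError):
    """A SyntheticTruth is internally inconsistent."""


@dataclass(frozen=True)
class LengthModel:
    """Locality mix and the standard-length -> scale-length map.

    ``locality_sl`` gives per-locality (mean, SD) of standard length in cm;
    ``locality_weights`` the sampling mix. Scale length is
    ``intercept + slope * SL + Normal(0, noise_sd)`` (mm), with ``noise_sd``
    chosen so the scale-length/standard-length Pearson correlation hits a
    target given the pooled SL spread.
    """

    locality_sl: Mapping[str, tuple[float, float]]
    locality_weights: Mapping[str, float]
    intercept: float = 0.4
    slope: float = 0.2
    noise_sd: float = 0.6

    def pooled_sl_mean(self) -> float:
        w = np.array([self.locality_weights[k] for k in self.locality_sl])
        w = w / w.sum()
        m = np.array([self.locality_sl[k][0] for k in self.locality_sl])
        return float(w @ m)

    def expected_scale_length(self) -> float:
        return self.intercept + self.slope * self.pooled_sl_mean()

    def with_target_correlation(self, r: float) -> "LengthModel":
        """Return a copy whose noise SD yields Pearson r between Lsc and SL."""
        if not 0 < r <= 1:
            raise TruthConfigError("target correlation must be in (0, 1]")
        w = np.array([self.locality_weights[k] for k in self.locality_sl])
        w = w / w.sum()
        means = np.array([self.locality_sl[k][0] for k in self.locality_sl])
        sds = np.array([self.locality_sl[k][1] for k in self.locality_sl])
        # pooled variance of SL across the locality mixture
        mu = float(w @ means)
        var = float(w @ (sds**2 + (means - mu) ** 2))
        if r == 1.0:
            noise = 0.0
        else:
            noise = abs(self.slope) * math.sqrt(var) * math.sqrt(1.0 / r**2 - 1.0)
        return replace(self, noise_sd=noise)


@dataclass(frozen=True)
class SyntheticTruth:
    """The generative parameter set a simulation is drawn from.

    ``alpha`` and the ``beta`` values live on the log (linear-predictor)
    scale; ``exp(beta[f])`` is the multiplicative effect of factor ``f`` on
    the expected mark count. ``sigma_alpha`` / ``sigma_beta`` are the
    between-individual deviations of the non-centred hierarchy, ``pi`` the
    zero-inflation weight, and ``status_probs`` the per-area probability that
    a sampled scale is damaged or regenerated.
    """

    species: str
    alpha: float
    sigma_alpha: float
    beta: Mapping[str, float]
    sigma_beta: Mapping[str, float]
    pi: float
    status_probs: Mapping[str, float]
    n_individuals: int
    length_model: LengthModel
    p_male: float = 0.5
    scales_per_area: tuple[int, int] = (3, 4)

    def __post_init__(self) -> None:
        if tuple(self.beta.keys()) != DESIGN_COLUMNS:
            raise TruthConfigError(
                f"beta keys must be exactly {DESIGN_COLUMNS}, got "
                f"{tuple(self.beta.keys())}"
            )
        unknown = set(self.sigma_beta) - set(WITHIN_INDIVIDUAL_FACTORS)
        if unknown:
            raise TruthConfigError(
                f"sigma_beta keys {sorted(unknown)} are not within-individual factors"
            )
        if not 0 <= self.pi < 1:
            raise TruthConfigError("pi must lie in [0, 1)")
        if self.sigma_alpha < 0 or any(v < 0 for v in self.sigma_beta.values()):
            raise TruthConfigError("deviation scales must be non-negative")
        if set(self.status_probs) != set(AREAS):
            raise TruthConfigError("status_probs must cover the nine areas")
        if any(not 0 <= p <= 1 for p in self.status_probs.values()):
            raise TruthConfigError("status probabilities must lie in [0, 1]")
        if not 0 <= self.p_male <= 1:
            raise TruthConfigError("p_male must lie in [0, 1]")
        if self.n_individuals < 1:
            raise TruthConfigError("n_individuals must be positive")
        lo, hi = self.scales_per_area
        if not (1 <= lo <= hi):
            raise TruthConfigError("scales_per_area must be an increasing range")

    @property
    def length_centre(self) -> float:
        """Scale-length value at which length_c = 0 in the generator."""
        return self.length_model.expected_scale_length()


@dataclass
class SimulationBundle:
    """A simulated dataset together with the truth it was drawn from."""

    dataset: ScaleDataset
    truth: SyntheticTruth
    individual_effects: dict[str, dict]
    seed: int

    def __post_init__(self) -> None:
        missing = set(self.dataset.specimen_ids) - set(self.individual_effects)
        if missing:
            raise TruthConfigError(
                f"specimens without realized effects: {sorted(missing)[:5]}"
            )


# --- study-shaped defaults ----------------------------------------------

# locality mixes: specimen counts and standard-length mean +- SD per locality,
# and observed sex ratios, as reported for the two study species
_CUREMA_LENGTHS = LengthModel(
    locality_sl={"LM": (22.4, 1.0), "TA": (23.8, 1.5), "CA": (24.3, 1.6), "ME": (22.5, 3.4)},
    locality_weights={"LM": 51, "TA": 46, "CA": 50, "ME": 53},
).with_target_correlation(0.6)

_CEPHALUS_LENGTHS = LengthModel(
    locality_sl={"SL": (27.0, 3.5), "SAB": (27.4, 2.9), "LM": (24.3, 1.7)},
    locality_weights={"SL": 50, "SAB": 22, "LM": 45},
).with_target_correlation(0.83)

# per-area damage/regeneration rates: anterior areas elevated for curema,
# ventral-anterior and ventral-central elevated for cephalus
_CUREMA_STATUS = {
    "AD": 0.19, "AM": 0.23, "AV": 0.23,
    "CD": 0.16, "CM": 0.20, "CV": 0.19,
    "PD": 0.15, "PM": 0.19, "PV": 0.16,
}
_CEPHALUS_STATUS = {
    "AD": 0.21, "AM": 0.11, "AV": 0.32,
    "CD": 0.19, "CM": 0.16, "CV": 0.34,
    "PD": 0.16, "PM": 0.10, "PV": 0.15,
}

_DEFAULT_SIGMA_BETA = {f: 0.05 for f in WITHIN_INDIVIDUAL_FACTORS}


def _beta_map(**nonzero: float) -> dict[str, float]:
    out = {c: 0.0 for c in DESIGN_COLUMNS}
    out.update(nonzero)
    return out


def species_preset(
    species: str,
    n_individuals: Optional[int] = None,
    pi: float = 0.0,
) -> SyntheticTruth:
    """Ground-truth presets carrying the effect sizes reported for each species.

    curema: males have 7% more marks than females, marks rise 6% per unit of
    scale length, ventral areas carry 7% more marks than the middle, and the
    horizontal-by-dorsal interactions add a small 3% effect; baseline mean
    count 3.37. cephalus: a negligible sex effect (x0.98), baseline 5.75, and
    area effects whose interaction pattern makes marks decrease
    anterior-to-posterior along the middle band but increase along the dorsal
    and ventral bands.
    """
    if species == "curema":
        return SyntheticTruth(
            species="curema",
            alpha=math.log(3.37),
            sigma_alpha=0.15,
            beta=_beta_map(
                sex_M=math.log(1.07),
                length_c=math.log(1.06),
                V_V=math.log(1.07),
                HxV_AD=math.log(1.03),
                HxV_PD=math.log(1.03),
            ),
            sigma_beta=dict(_DEFAULT_SIGMA_BETA),
            pi=pi,
            status_probs=dict(_CUREMA_STATUS),
            n_individuals=200 if n_individuals is None else n_individuals,
            length_model=_CUREMA_LENGTHS,
            p_male=47 / 200,
        )
    if species == "cephalus":
        return SyntheticTruth(
            species="cephalus",
            alpha=math.log(5.75),
            sigma_alpha=0.15,
            beta=_beta_map(
                sex_M=math.log(0.98),
                length_c=math.log(1.06),
                H_A=math.log(1.07),
                H_P=math.log(0.93),
                V_D=math.log(1.05),
                V_V=math.log(1.05),
                HxV_AD=math.log(0.88),
                HxV_AV=math.log(0.88),
                HxV_PD=math.log(1.15),
                HxV_PV=math.log(1.15),
            ),
            sigma_beta=dict(_DEFAULT_SIGMA_BETA),
            pi=pi,
            status_probs=dict(_CEPHALUS_STATUS),
            n_individuals=117 if n_individuals is None else n_individuals,
            length_model=_CEPHALUS_LENGTHS,
            p_male=53 / 117,
        )
    raise TruthConfigError(f"unknown species {species!r}")


def _design_row(sex: str, area: str, length_c: float) -> dict[str, float]:
    h, v = area[0], area[1]
    row = {c: 0.0 for c in DESIGN_COLUMNS}
    row["sex_M"] = 1.0 if sex == "M" else 0.0
    row["length_c"] = length_c
    if h in ("A", "P"):
        row[f"H_{h}"] = 1.0
    if v in ("D", "V"):
        row[f"V_{v}"] = 1.0
    if h in ("A", "P") and v in ("D", "V"):
        row[f"HxV_{h}{v}"] = 1.0
    return row


def simulate_dataset(truth: SyntheticTruth, seed: int) -> SimulationBundle:
    """Draw a full study-shaped dataset from the generative model.

    For each individual the non-centred hierarchy is realized explicitly:
    a standard-normal intercept offset scaled by ``sigma_alpha`` and, for each
    within-individual factor with a positive ``sigma_beta``, a standard-normal
    slope offset scaled by that factor's deviation. Every scale then gets a
    status from the per-area damage rates, and good scales get a mark count
    from ZIPoisson(pi, exp(eta)).
    """
    rng = np.random.default_rng(seed)
    lm = truth.length_model
    locs = list(lm.locality_sl)
    weights = np.array([lm.locality_weights[k] for k in locs], dtype=float)
    weights /= weights.sum()
    centre = truth.length_centre
    tag = truth.species[:3]

    records: list[ScaleRecord] = []
    effects: dict[str, dict] = {}
    lo, hi = truth.scales_per_area

    for i in range(truth.n_individuals):
        sid = f"{tag}{i + 1:04d}"
        locality = locs[rng.choice(len(locs), p=weights)]
        sex = "M" if rng.random() < truth.p_male else "F"
        mu_sl, sd_sl = lm.locality_sl[locality]
        sl = float(max(rng.normal(mu_sl, sd_sl), 1.0))

        d_alpha = float(rng.standard_normal())
        alpha_i = truth.alpha + d_alpha * truth.sigma_alpha
        beta_i = dict(truth.beta)
        d_beta: dict[str, float] = {}
        for f, s in truth.sigma_beta.items():
            d = float(rng.standard_normal())
            d_beta[f] = d
            beta_i[f] = truth.beta[f] + d * s
        effects[sid] = {
            "alpha_i": alpha_i,
            "delta_alpha": d_alpha,
            "beta_i": beta_i,
            "delta_beta": d_beta,
        }

        for area in AREAS:
            n_scales = int(rng.integers(lo, hi + 1))
            p_bad = truth.status_probs[area]
            for _ in range(n_scales):
                lsc = float(max(lm.intercept + lm.slope * sl + rng.normal(0, lm.noise_sd), 0.05))
                wsc = float(max(lsc * rng.normal(0.72, 0.03), 0.01))
                rad = float(max(lsc * rng.normal(0.55, 0.03), 0.01))
                if rng.random() < p_bad:
                    status = "damaged" if rng.random() < 0.5 else "regenerated"
                    marks = None
                else:
                    status = "good"
                    row = _design_row(sex, area, lsc - centre)
                    eta = alpha_i + sum(row[c] * beta_i[c] for c in DESIGN_COLUMNS)
                    lam = math.exp(eta)
                    if truth.pi > 0 and rng.random() < truth.pi:
                        marks = 0
                    else:
                        marks = int(rng.poisson(lam))
                records.append(
                    ScaleRecord(
                        specimen_id=sid,
                        species=truth.species,
                        locality=locality,
                        sex=sex,
                        standard_length=round(sl, 4),
                        area=area,
                        scale_length=round(lsc, 4),
                        scale_width=round(wsc, 4),
                        scale_radius=round(rad, 4),
                        status=status,
                        marks=marks,
                    )
                )

    dataset = ScaleDataset(
        records,
        metadata={
            "generator": "scalemarks.simulate",
            "species": truth.species,
            "seed": seed,
            "length_centre": centre,
        },
    )
    return SimulationBundle(dataset=dataset, truth=truth, individual_effects=effects, seed=seed)


# --- flat TOML-style (de)serialization of a truth -------------------------


def truth_to_toml(truth: SyntheticTruth) -> str:
    """Serialize a truth as a flat key-value TOML document."""
    lines = [
        f'species = "{truth.species}"',
        f"alpha = {truth.alpha!r}",
        f"sigma_alpha = {truth.sigma_alpha!r}",
        f"pi = {truth.pi!r}",
        f"n_individuals = {truth.n_individuals}",
        f"p_male = {truth.p_male!r}",
        f"scales_per_area = [{truth.scales_per_area[0]}, {truth.scales_per_area[1]}]",
    ]
    for f in DESIGN_COLUMNS:
        lines.append(f"beta_{f} = {truth.beta[f]!r}")
    for f, s in truth.sigma_beta.items():
        lines.append(f"sigma_beta_{f} = {s!r}")
    for a in AREAS:
        lines.append(f"status_prob_{a} = {truth.status_probs[a]!r}")
    lm = truth.length_model
    lines.append(f"length_intercept = {lm.intercept!r}")
    lines.append(f"length_slope = {lm.slope!r}")
    lines.append(f"length_noise_sd = {lm.noise_sd!r}")
    for loc, (m, s) in lm.locality_sl.items():
        lines.append(f"locality_{loc} = [{m!r}, {s!r}, {lm.locality_weights[loc]!r}]")
    return "\n".join(lines) + "\n"


def truth_from_toml(text: str) -> SyntheticTruth:
    """Parse a truth from the flat TOML produced by :func:`truth_to_toml`."""
    import tomllib

    data = tomllib.loads(text)
    beta = {f: float(data[f"beta_{f}"]) for f in DESIGN_COLUMNS}
    sigma_beta = {
        f: float(data[k])
        for f in WITHIN_INDIVIDUAL_FACTORS
        if (k := f"sigma_beta_{f}") in data
    }
    status = {a: float(data[f"status_prob_{a}"]) for a in AREAS}
    locality_sl = {}
    locality_weights = {}
    for key, val in data.items():
        if key.startswith("locality_"):
            loc = key[len("locality_"):]
            locality_sl[loc] = (float(val[0]), float(val[1]))
            locality_weights[loc] = float(val[2])
    lm = LengthModel(
        locality_sl=locality_sl,
        locality_weights=locality_weights,
        intercept=float(data["length_intercept"]),
        slope=float(data["length_slope"]),
        noise_sd=float(data["length_noise_sd"]),
    )
    spa = data.get("scales_per_area", [3, 4])
    return SyntheticTruth(
        species=data["species"],
        alpha=float(data["alpha"]),
        sigma_alpha=float(data["sigma_alpha"]),
        beta=beta,
        sigma_beta=sigma_beta,
        pi=float(data["pi"]),
        status_probs=status,
        n_individuals=int(data["n_individuals"]),
        length_model=lm,
        p_male=float(data["p_male"]),
        scales_per_area=(int(spa[0]), int(spa[1])),
    )
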