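"""Synthetic survey-like cohorts and idealized binormal score sets.

The cohort generator draws nine correlated physiological variables per
subject through a Gaussian copula, then shifts them along a single
latent "metabolic risk" factor so that central obesity, dyslipidemia,
hypertension and hyperglycemia co-occur the way they do in real survey
data.  That co-occurrence is what makes the surrogate indices
informative about rule-based metabolic syndrome, which is the property
the downstream tests need.  Default parameters put the cohort medians
near BMI 28.4 kg/m^2, waist 95.8 cm, TG 168 mg/dL, glucose 92 mg/dL and
HDL 43 mg/dL, with a MetS prevalence in the 40-60% band.

Triglycerides and glucose are log-normal (right-skewed); the remaining
variables are clipped normals.  All randomness flows from one seed
through named sub-streams, so adding a field never perturbs existing
draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cohort import FEMALE, MALE, ParticipantRecord

#: Copula variable order.  "weight" and "height" jointly determine BMI.
VARIABLES = ("weight", "height", "wc", "sbp", "dbp", "chol", "hdl", "tg", "glu")

#: Fixed spawn keys for the named RNG sub-streams.
_STREAMS = {"sex": 0, "age": 1, "latent": 2, "copula": 3, "flags": 4, "missing": 5}


def _default_corr() -> list[list[float]]:
    """Residual (pre-latent-factor) correlations among the nine variables."""
    corr = np.eye(len(VARIABLES))
    pairs = {
        ("weight", "height"): 0.45,
        ("weight", "wc"): 0.75,
        ("weight", "sbp"): 0.15,
        ("weight", "dbp"): 0.10,
        ("height", "wc"): 0.05,
        ("wc", "sbp"): 0.15,
        ("wc", "dbp"): 0.10,
        ("wc", "tg"): 0.10,
        ("wc", "hdl"): -0.10,
        ("wc", "glu"): 0.10,
        ("sbp", "dbp"): 0.65,
        ("chol", "tg"): 0.30,
        ("chol", "hdl"): 0.10,
        ("chol", "glu"): 0.05,
        ("hdl", "tg"): -0.35,
        ("tg", "glu"): 0.15,
    }
    index = {v: i for i, v in enumerate(VARIABLES)}
    for (a, b), r in pairs.items():
        corr[index[a], index[b]] = corr[index[b], index[a]] = r
    return corr.tolist()


# Marginal parameters: dist is "normal" (loc/scale, clipped at lo) or
# "lognormal" (loc = median, scale = log-sd).
_DEFAULT_MARGINALS = {
    MALE: {
        "weight": ("normal", 79.0, 14.0, 35.0),
        "height": ("normal", 1.67, 0.07, 1.31),
        "wc": ("normal", 97.5, 12.0, 55.0),
        "sbp": ("normal", 122.0, 19.0, 75.0),
        "dbp": ("normal", 76.0, 11.0, 40.0),
        "chol": ("normal", 185.0, 38.0, 70.0),
        "hdl": ("normal", 41.0, 9.5, 15.0),
        "tg": ("lognormal", 175.0, 0.42, 40.0),
        "glu": ("lognormal", 92.0, 0.16, 71.0),
    },
    FEMALE: {
        "weight": ("normal", 69.0, 13.0, 32.0),
        "height": ("normal", 1.555, 0.065, 1.31),
        "wc": ("normal", 95.0, 13.0, 50.0),
        "sbp": ("normal", 121.0, 19.0, 75.0),
        "dbp": ("normal", 74.0, 11.0, 40.0),
        "chol": ("normal", 182.0, 38.0, 70.0),
        "hdl": ("normal", 44.5, 10.5, 15.0),
        "tg": ("lognormal", 163.0, 0.42, 40.0),
        "glu": ("lognormal", 92.0, 0.16, 71.0),
    },
}

#: Loadings of the latent risk factor on each variable's standardized
#: (or log) scale.  HDL loads negatively: risk depresses it.
_DEFAULT_LOADINGS = {
    "weight": 0.35, "height": 0.0, "wc": 0.45, "sbp": 0.40, "dbp": 0.40,
    "chol": 0.15, "hdl": -0.40, "tg": 0.35, "glu": 0.14,
}

#: Component thresholds used for conditional flag sampling.
_FLAG_RULES = {
    "dx_diabetes": ("glu", 110.0),
    "dx_hypertension": ("sbp", 130.0),
    "tx_triglycerides": ("tg", 150.0),
    "dx_hypercholesterolemia": ("chol", 200.0),
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    n: int = 10_000
    seed: int = 0
    sex_ratio_female: float = 0.571
    age_group_weights: Sequence[float] = (0.379, 0.387, 0.234)
    age_ranges: Sequence[Sequence[int]] = ((20, 39), (40, 59), (60, 85))
    marginals: dict = field(default_factory=lambda: {
        sex: dict(params) for sex, params in _DEFAULT_MARGINALS.items()})
    corr: list = field(default_factory=_default_corr)
    latent_risk_sd: float = 1.0
    loadings: dict = field(default_factory=lambda: dict(_DEFAULT_LOADINGS))
    p_flag_given_component: float = 0.30
    p_flag_given_no_component: float = 0.02

    def validate(self) -> None:
        corr = np.asarray(self.corr, dtype=float)
        k = len(VARIABLES)
        if corr.shape != (k, k) or not np.allclose(corr, corr.T):
            raise ValueError("copula matrix must be symmetric KxK over the nine variables")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("copula matrix is not positive-definite")
        for p in (self.sex_ratio_female, self.p_flag_given_component,
                  self.p_flag_given_no_component):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.latent_risk_sd < 0:
            raise ValueError("latent_risk_sd must be non-negative")
        if abs(sum(self.age_group_weights) - 1.0) > 1e-9:
            raise ValueError("age group weights must sum to 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        spec = cls(**json.loads(text))
        # JSON has no tuples; restore the canonical in-memory shapes
        spec.age_group_weights = tuple(spec.age_group_weights)
        spec.age_ranges = tuple(tuple(r) for r in spec.age_ranges)
        spec.marginals = {sex: {v: tuple(p) for v, p in m.items()}
                          for sex, m in spec.marginals.items()}
        return spec


@dataclass(frozen=True)
class BinormalSpec:
    """Scores with a known ROC: negatives N(0,1), positives N(d,1)."""

    n_pos: int
    n_neg: int
    d: float
    seed: int = 0

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("d must be non-negative")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one subject")

    @property
    def true_auc(self) -> float:
        from scipy.stats import norm
        return float(norm.cdf(self.d / np.sqrt(2.0)))

    @property
    def true_max_youden(self) -> float:
        """Maximal Se + Sp - 1, attained at the midpoint threshold d/2."""
        from scipy.stats import norm
        return float(2.0 * norm.cdf(self.d / 2.0) - 1.0)


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[name],)))


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Draw a reproducible synthetic cohort under ``spec``."""
    spec.validate()
    n = spec.n
    female = _stream(spec.seed, "sex").random(n) < spec.sex_ratio_female
    sexes = np.where(female, FEMALE, MALE)

    rng_age = _stream(spec.seed, "age")
    groups = rng_age.choice(len(spec.age_group_weights), size=n, p=list(spec.age_group_weights))
    lo = np.array([r[0] for r in spec.age_ranges])[groups]
    hi = np.array([r[1] for r in spec.age_ranges])[groups]
    ages = rng_age.integers(lo, hi + 1)

    z = spec.latent_risk_sd * _stream(spec.seed, "latent").standard_normal(n)
    corr = np.asarray(spec.corr, dtype=float)
    u = _stream(spec.seed, "copula").multivariate_normal(
        np.zeros(len(VARIABLES)), corr, size=n, method="cholesky")

    columns: dict[str, np.ndarray] = {}
    for j, var in enumerate(VARIABLES):
        v = u[:, j] + spec.loadings.get(var, 0.0) * z
        out = np.empty(n)
        for sex in (MALE, FEMALE):
            mask = sexes == sex
            dist, loc, scale, clip_lo = spec.marginals[sex][var]
            if dist == "normal":
                out[mask] = np.maximum(loc + scale * v[mask], clip_lo)
            elif dist == "lognormal":
                out[mask] = np.maximum(loc * np.exp(scale * v[mask]), clip_lo)
            else:
                raise ValueError(f"unknown marginal distribution {dist!r}")
        columns[var] = out

    rng_flags = _stream(spec.seed, "flags")
    flags: dict[str, np.ndarray] = {}
    for flag_name in ("dx_diabetes", "dx_hypertension", "tx_triglycerides",
                      "dx_hypercholesterolemia"):
        var, cut = _FLAG_RULES[flag_name]
        p = np.where(columns[var] >= cut,
                     spec.p_flag_given_component, spec.p_flag_given_no_component)
        flags[flag_name] = rng_flags.random(n) < p

    records = []
    for i in range(n):
        weight = float(columns["weight"][i])
        height = float(columns["height"][i])
        records.append(ParticipantRecord(
            id=f"S{i:06d}",
            sex=str(sexes[i]),
            age=int(ages[i]),
            weight=round(weight, 2),
            height=round(height, 3),
            bmi=None,
            wc=round(float(columns["wc"][i]), 1),
            sbp=round(float(columns["sbp"][i]), 0),
            dbp=round(float(columns["dbp"][i]), 0),
            chol_total=round(float(columns["chol"][i]), 1),
            hdl=round(float(columns["hdl"][i]), 1),
            tg=round(float(columns["tg"][i]), 1),
            glu=round(float(columns["glu"][i]), 1),
            dx_diabetes=bool(flags["dx_diabetes"][i]),
            dx_hypertension=bool(flags["dx_hypertension"][i]),
            tx_triglycerides=bool(flags["tx_triglycerides"][i]),
            dx_hypercholesterolemia=bool(flags["dx_hypercholesterolemia"][i]),
        ))
    return records


def generate_binormal_scores(spec: BinormalSpec) -> tuple[np.ndarray, np.ndarray]:
    """Scores and boolean labels: negatives N(0,1), positives N(d,1)."""
    rng = np.random.default_rng(spec.seed)
    neg = rng.standard_normal(spec.n_neg)
    pos = spec.d + rng.standard_normal(spec.n_pos)
    scores = np.concatenate([neg, pos])
    labels = np.concatenate([np.zeros(spec.n_neg, bool), np.ones(spec.n_pos, bool)])
    return scores, labels


#: Fields eligible for blanking when simulating incomplete survey extracts.
MISSABLE_FIELDS = ("weight", "height", "wc", "sbp", "dbp",
                   "chol_total", "hdl", "tg", "glu")


def inject_missingness(records: Iterable[ParticipantRecord], rate: float,
                       seed: int, fields: Sequence[str] = MISSABLE_FIELDS) -> list[ParticipantRecord]:
    """Independently blank each eligible field with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    records = list(records)
    if rate == 0.0:
        return records
    rng = _stream(seed, "missing")
    mask = rng.random((len(records), len(fields))) < rate
    out = []
    for i, r in enumerate(records):
        blanked = {f: None for k, f in enumerate(fields) if mask[i, k]}
        out.append(dataclasses.replace(r, **blanked) if blanked else r)
    return out
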