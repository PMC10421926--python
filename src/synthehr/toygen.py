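"""Seeded simulator of heterogeneous EHR-like cohorts with known ground truth.

The generator emulates the structure of inpatient EHR cohorts: skewed and
discrete-grid numeric features, nonuniform categoricals, variable sequence
lengths, high per-feature missingness (optionally severity-dependent), and
a low-prevalence binary outcome driven by a latent severity plus chosen
covariates.  Because every law is declared in the config, fitted models and
metrics can be checked against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import EHRDataset, MaskSet, derive_masks
from .schema import FeatureSchema

# --- feature laws --------------------------------------------------------


@dataclass(frozen=True)
class NumericLaw:
    """Declarative sampler for one numeric feature.

    kinds:
      gamma:       shape/scale/shift              (skewed continuous)
      lognormal:   mu/sigma/shift                 (heavy right tail)
      normal:      mu/sigma
      grid:        values + probs                 (discrete jumps, e.g. multiples of 5)
      mixture:     two normals with weights       (bimodal)
    ``severity_weight`` shifts the location with the patient's latent severity.
    """

    kind: str
    params: dict = field(default_factory=dict)
    severity_weight: float = 0.0
    round_to: float | None = None

    def sample(self, rng: np.random.Generator, size, severity: np.ndarray) -> np.ndarray:
        p = self.params
        if self.kind == "gamma":
            x = rng.gamma(p["shape"], p["scale"], size=size) + p.get("shift", 0.0)
        elif self.kind == "lognormal":
            x = rng.lognormal(p["mu"], p["sigma"], size=size) + p.get("shift", 0.0)
        elif self.kind == "normal":
            x = rng.normal(p["mu"], p["sigma"], size=size)
        elif self.kind == "grid":
            vals = np.asarray(p["values"], dtype=np.float64)
            x = rng.choice(vals, size=size, p=p.get("probs"))
        elif self.kind == "mixture":
            comp = rng.random(size=size) < p["weight"]
            x = np.where(comp,
                         rng.normal(p["mu1"], p["sigma1"], size=size),
                         rng.normal(p["mu2"], p["sigma2"], size=size))
        else:
            raise ValueError(f"unknown numeric law {self.kind!r}")
        if self.severity_weight and self.kind != "grid":
            x = x + self.severity_weight * np.broadcast_to(severity, np.shape(x))
        if self.round_to:
            x = np.round(x / self.round_to) * self.round_to
        return x


@dataclass(frozen=True)
class CategoricalLaw:
    vocabulary: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("categorical probabilities must sum to 1")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        return rng.choice(len(self.vocabulary), size=size, p=np.asarray(self.probs))


@dataclass
class ToyConfig:
    n_patients: int = 2000
    t_max: int = 30
    mean_length: float = 9.0             # lengths ~ 1 + Poisson, clipped to [1, t_max]
    time_gap_scale: float = 4.0          # exponential inter-measurement gaps (hours)
    static_numeric: dict[str, NumericLaw] = field(default_factory=dict)
    static_categorical: dict[str, CategoricalLaw] = field(default_factory=dict)
    temporal_numeric: dict[str, NumericLaw] = field(default_factory=dict)
    temporal_categorical: dict[str, CategoricalLaw] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)  # per temporal numeric/categorical
    static_missing_rates: dict[str, float] = field(default_factory=dict)
    mar_strength: float = 0.0            # >0: missingness depends on latent severity
    outcome_name: str = "mortality"      # generated as a static numeric in {0,1}
    outcome_prevalence: float = 0.10
    outcome_coef_severity: float = 1.2   # planted signal; 0 => outcome independent
    outcome_coef_age: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for r in list(self.missing_rates.values()) + list(self.static_missing_rates.values()):
            if not (0.0 <= r <= 1.0):
                raise ValueError("missing rates must lie in [0, 1]")
        if not (0.0 < self.outcome_prevalence < 1.0):
            raise ValueError("outcome prevalence must lie strictly in (0, 1): "
                             "a logistic outcome model cannot reach 0 or 1")

    def schema(self) -> FeatureSchema:
        return FeatureSchema(
            static_numeric=tuple(self.static_numeric) + (self.outcome_name,),
            static_categorical=tuple((n, law.vocabulary) for n, law in self.static_categorical.items()),
            temporal_numeric=tuple(self.temporal_numeric),
            temporal_categorical=tuple((n, law.vocabulary) for n, law in self.temporal_categorical.items()),
            time_name="time",
            max_seq_len=self.t_max,
        )


def default_mimic_like(seed: int = 0, n_patients: int = 2000) -> ToyConfig:
    """Preset echoing the shape of a critical-care cohort at reduced width.

    3 static numerics (skewed age, grid-valued weight, binary outcome),
    3 nonuniform static categoricals, 10 temporal numerics mixing smooth,
    skewed and grid-valued laws with missingness 0.3-0.8, 2 temporal
    categoricals, sequence lengths 1-30.
    """
    sn = {
        "age": NumericLaw("gamma", {"shape": 9.0, "scale": 5.0, "shift": 20.0}),
        "admission_weight": NumericLaw("grid", {
            "values": [float(v) for v in range(40, 185, 5)],
        }),
    }
    sc = {
        "gender": CategoricalLaw(("F", "M"), (0.55, 0.45)),
        "admission_type": CategoricalLaw(("emergency", "elective", "urgent"), (0.7, 0.2, 0.1)),
        "marital_status": CategoricalLaw(("married", "single", "widowed", "divorced", "unknown"),
                                         (0.42, 0.3, 0.13, 0.1, 0.05)),
    }
    tn = {
        "heart_rate": NumericLaw("normal", {"mu": 82.0, "sigma": 12.0}, severity_weight=6.0),
        "respiratory_rate": NumericLaw("normal", {"mu": 19.0, "sigma": 4.0}, severity_weight=1.5),
        "spo2": NumericLaw("normal", {"mu": 97.0, "sigma": 2.5}, severity_weight=-1.0),
        "nbp_systolic": NumericLaw("normal", {"mu": 120.0, "sigma": 18.0}, severity_weight=-5.0),
        "nbp_diastolic": NumericLaw("normal", {"mu": 57.0, "sigma": 12.0}, severity_weight=-3.0),
        "glucose": NumericLaw("lognormal", {"mu": 4.9, "sigma": 0.35}),
        "creatinine": NumericLaw("lognormal", {"mu": 0.2, "sigma": 0.5}),
        "resp_pressure": NumericLaw("normal", {"mu": 42.0, "sigma": 7.0}, round_to=5.0),
        "hr_alarm_low": NumericLaw("grid", {"values": [45.0, 50.0, 55.0, 60.0],
                                            "probs": [0.2, 0.5, 0.2, 0.1]}),
        "lactate": NumericLaw("mixture", {"weight": 0.8, "mu1": 1.4, "sigma1": 0.4,
                                          "mu2": 4.5, "sigma2": 1.2}, severity_weight=0.4),
    }
    tc = {
        "heart_rhythm": CategoricalLaw(("sinus", "afib", "paced", "other"), (0.68, 0.2, 0.07, 0.05)),
        "o2_device": CategoricalLaw(("none", "cannula", "ventilator"), (0.55, 0.3, 0.15)),
    }
    rates = {
        "heart_rate": 0.30, "respiratory_rate": 0.35, "spo2": 0.40,
        "nbp_systolic": 0.55, "nbp_diastolic": 0.55, "glucose": 0.65,
        "creatinine": 0.75, "resp_pressure": 0.60, "hr_alarm_low": 0.70,
        "lactate": 0.80, "heart_rhythm": 0.45, "o2_device": 0.50,
    }
    return ToyConfig(
        n_patients=n_patients, t_max=30, mean_length=9.0,
        static_numeric=sn, static_categorical=sc,
        temporal_numeric=tn, temporal_categorical=tc,
        missing_rates=rates,
        static_missing_rates={"admission_weight": 0.15, "marital_status": 0.10},
        seed=seed,
    )


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(expit(b0 + lin)) == target prevalence."""
    f = lambda b0: expit(b0 + lin).mean() - target  # noqa: E731
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("outcome model cannot reach the requested prevalence")
    return brentq(f, lo, hi, xtol=1e-10)


def generate_cohort(config: ToyConfig) -> tuple[EHRDataset, MaskSet, dict]:
    """Draw a cohort; returns (dataset, masks, ground_truth).

    ``ground_truth`` carries the config, the schema, the latent severity,
    the outcome linear predictor and the calibrated intercept.
    """
    rng = np.random.default_rng(config.seed)
    N, T = config.n_patients, config.t_max
    schema = config.schema()
    severity = rng.standard_normal(N)

    # static numerics (+ outcome appended last)
    Sn = len(schema.static_numeric)
    static_num = np.full((N, Sn), np.nan)
    for j, name in enumerate(config.static_numeric):
        static_num[:, j] = config.static_numeric[name].sample(rng, N, severity)
    # outcome: logistic on severity and standardized age-like first feature
    first = static_num[:, 0]
    z_first = (first - first.mean()) / (first.std() + 1e-12)
    lin = config.outcome_coef_severity * severity + config.outcome_coef_age * z_first
    b0 = _calibrate_intercept(lin, config.outcome_prevalence)
    outcome = (rng.random(N) < expit(b0 + lin)).astype(np.float64)
    static_num[:, Sn - 1] = outcome

    static_cat = np.full((N, len(schema.static_categorical)), -1, dtype=np.int64)
    for j, (name, law) in enumerate(config.static_categorical.items()):
        static_cat[:, j] = law.sample(rng, N)

    lengths = np.clip(1 + rng.poisson(config.mean_length - 1.0, size=N), 1, T).astype(np.int64)
    gaps = rng.exponential(config.time_gap_scale, size=(N, T))
    times = np.cumsum(gaps, axis=1)
    step_mask = np.arange(T)[None, :] < lengths[:, None]
    times = np.where(step_mask, times, 0.0)

    temp_num = np.full((N, T, len(schema.temporal_numeric)), np.nan)
    for j, (name, law) in enumerate(config.temporal_numeric.items()):
        temp_num[:, :, j] = law.sample(rng, (N, T), severity[:, None])
    temp_cat = np.full((N, T, len(schema.temporal_categorical)), -1, dtype=np.int64)
    for j, (name, law) in enumerate(config.temporal_categorical.items()):
        temp_cat[:, :, j] = law.sample(rng, (N, T))

    # missingness: MCAR base rate, optionally tilted by severity (MAR)
    def miss_prob(base: float) -> np.ndarray:
        if config.mar_strength == 0.0 or base in (0.0, 1.0):
            return np.full(N, base)
        logit = np.log(base / (1 - base)) + config.mar_strength * severity
        return expit(logit)

    for j, name in enumerate(config.temporal_numeric):
        p = miss_prob(config.missing_rates.get(name, 0.0))
        drop = rng.random((N, T)) < p[:, None]
        temp_num[:, :, j] = np.where(drop, np.nan, temp_num[:, :, j])
    for j, name in enumerate(config.temporal_categorical):
        p = miss_prob(config.missing_rates.get(name, 0.0))
        drop = rng.random((N, T)) < p[:, None]
        temp_cat[:, :, j] = np.where(drop, -1, temp_cat[:, :, j])
    for j, name in enumerate(config.static_numeric):
        base = config.static_missing_rates.get(name, 0.0)
        if base:
            static_num[:, j] = np.where(rng.random(N) < base, np.nan, static_num[:, j])
    for j, name in enumerate(config.static_categorical):
        base = config.static_missing_rates.get(name, 0.0)
        if base:
            static_cat[:, j] = np.where(rng.random(N) < base, -1, static_cat[:, j])

    # blank out everything beyond each patient's length
    temp_num[~step_mask] = np.nan
    temp_cat[~step_mask] = -1

    ids = np.array([f"p{i:06d}" for i in range(N)], dtype=object)
    dataset = EHRDataset(ids, static_num, static_cat, times, temp_num, temp_cat, lengths)
    masks = derive_masks(dataset)
    ground_truth = {
        "config": config,
        "schema": schema,
        "severity": severity,
        "outcome_intercept": b0,
        "outcome_linear": lin,
    }
    return dataset, masks, ground_truth
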