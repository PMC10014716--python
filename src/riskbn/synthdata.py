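"""Seeded two-country synthetic survey generator.

Generates cross-sectional mental-health survey samples (demographics,
PHQ-9 items, GAD-7, PSS-10 subscales, ISI, loneliness, CD-RISC-10,
WHOQOL-BREF domains, exercise, illness) whose marginal moments, outcome
prevalence and depression-conditional prevalence are calibrated to the
published sample statistics of the Austrian (n = 1,005) and UK (n = 1,006)
COVID-19 lockdown surveys.

Mechanism
---------
A Gaussian copula couples latent psychological traits (depression,
anxiety, helplessness, insomnia, loneliness, self-efficacy, resilience,
four quality-of-life domains, exercise, household size).  Each observed
scale score is the trait quantile-mapped onto a moment-matched bounded
discrete distribution (:mod:`riskbn._discrete`).  PHQ-9 item 9 — the
suicidal-ideation item — is drawn from a logistic model on the
standardized traits; its severity grade (1/2/3 given endorsement) follows
a fixed decreasing split.  Calibration adjusts the logistic intercept, the
depression-trait coefficient and a tail tilt of the PHQ-8 marginal by
alternating bisection until the marginal SI prevalence, the prevalence
among the depressed (PHQ-9 >= 10) and the depression rate itself match
their targets on a large Monte-Carlo sample.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from ._discrete import DiscreteScaleDistribution

__all__ = [
    "ScaleSpec",
    "OutcomeModel",
    "CalibrationTargets",
    "GeneratorConfig",
    "ConfigurationError",
    "CalibrationError",
    "default_config",
    "calibrate_outcome_model",
    "calibrated_config",
    "generate_survey",
    "derive_item9",
    "simulate_prevalences",
    "write_survey_csv",
    "SCHEMA_COLUMNS",
    "TRAITS",
    "CATEGORY_LEVELS",
]


class ConfigurationError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


# ---------------------------------------------------------------- schema

SCHEMA_COLUMNS = [
    "country", "age_group", "gender", "education", "children", "employment",
    "income_band", "housing", "occupants", "illness", "exercise_days",
    "phq_i1", "phq_i2", "phq_i3", "phq_i4", "phq_i5", "phq_i6", "phq_i7",
    "phq_i8", "phq_i9", "gad7", "pss_helplessness", "pss_selfefficacy",
    "isi", "loneliness", "cdrisc", "whoqol_physical", "whoqol_psychological",
    "whoqol_relationships", "whoqol_environment",
]

CATEGORY_LEVELS = {
    "age_group": ["18-24", "25-34", "35-44", "45-54", "55-64", "65+"],
    "gender": ["female", "male"],
    "education": ["none", "elementary", "high_school", "vocational",
                  "college", "university"],
    "employment": ["unemployed", "employed", "retired"],
    "income_band": ["band_1", "band_2", "band_3", "band_4", "band_5"],
    "housing": ["flat", "apartment_terrace", "house"],
}

TRAITS = [
    "depression", "anxiety", "helplessness", "insomnia", "loneliness",
    "self_efficacy", "resilience", "qol_physical", "qol_psychological",
    "qol_relationships", "qol_environment", "exercise", "household",
]

_RISK = {"depression", "anxiety", "helplessness", "insomnia", "loneliness"}
_PROTECTIVE = {"self_efficacy", "resilience", "qol_physical",
               "qol_psychological", "qol_relationships", "qol_environment",
               "exercise"}

#: scale column -> driving latent trait
SCALE_TRAIT = {
    "phq8": "depression",
    "gad7": "anxiety",
    "pss_helplessness": "helplessness",
    "pss_selfefficacy": "self_efficacy",
    "isi": "insomnia",
    "loneliness": "loneliness",
    "cdrisc": "resilience",
    "whoqol_physical": "qol_physical",
    "whoqol_psychological": "qol_psychological",
    "whoqol_relationships": "qol_relationships",
    "whoqol_environment": "qol_environment",
    "exercise_days": "exercise",
    "occupants": "household",
}

SCALE_SUPPORT = {
    "phq8": (0, 24), "gad7": (0, 21), "pss_helplessness": (0, 24),
    "pss_selfefficacy": (0, 16), "isi": (0, 28), "loneliness": (0, 11),
    "cdrisc": (0, 40), "whoqol_physical": (4, 20),
    "whoqol_psychological": (4, 20), "whoqol_relationships": (4, 20),
    "whoqol_environment": (4, 20), "exercise_days": (0, 7),
    "occupants": (0, 10),
}

# printed sample statistics: column -> (mean, sd) per country
_SCALE_MOMENTS = {
    "austria": {
        "phq8": (5.93, 5.00), "gad7": (5.84, 4.70),
        "pss_helplessness": (9.37, 5.19), "pss_selfefficacy": (9.40, 3.13),
        "isi": (8.31, 5.70), "loneliness": (4.58, 3.67),
        "cdrisc": (27.27, 7.20), "whoqol_physical": (15.57, 2.77),
        "whoqol_psychological": (15.17, 2.99),
        "whoqol_relationships": (14.41, 3.47),
        "whoqol_environment": (15.96, 2.43), "exercise_days": (2.70, 1.44),
        "occupants": (1.74, 1.34),
    },
    "uk": {
        "phq8": (8.38, 6.99), "gad7": (8.03, 6.52),
        "pss_helplessness": (10.34, 6.05), "pss_selfefficacy": (8.63, 3.42),
        "isi": (10.43, 7.05), "loneliness": (6.41, 3.21),
        "cdrisc": (24.56, 8.12), "whoqol_physical": (14.58, 3.31),
        "whoqol_psychological": (13.38, 3.42),
        "whoqol_relationships": (13.67, 3.83),
        "whoqol_environment": (14.35, 2.97), "exercise_days": (2.29, 1.59),
        "occupants": (1.89, 1.43),
    },
}

_DEMOGRAPHICS = {
    "austria": {
        "age_group": [0.117, 0.165, 0.184, 0.221, 0.180, 0.132],
        "gender": [0.527, 0.473],
        "education": [0.000, 0.001, 0.026, 0.319, 0.287, 0.367],
        "employment": [0.268, 0.558, 0.174],
        "income_band": [0.071, 0.234, 0.302, 0.195, 0.198],
        "housing": [0.232, 0.344, 0.424],
        "children": 0.237,
        "illness": 0.069,
    },
    "uk": {
        "age_group": [0.097, 0.202, 0.189, 0.193, 0.172, 0.147],
        "gender": [0.541, 0.459],
        "education": [0.016, 0.035, 0.403, 0.142, 0.128, 0.276],
        "employment": [0.475, 0.385, 0.140],
        "income_band": [0.137, 0.341, 0.254, 0.146, 0.121],
        "housing": [0.201, 0.056, 0.744],
        "children": 0.306,
        "illness": 0.103,
    },
}

_PREVALENCES = {
    # (p_si, p_si_dep, p_si_nondep)
    "austria": (0.173, 0.550, 0.073),
    "uk": (0.317, 0.645, 0.088),
}

#: default outcome coefficients on standardized latent traits (logit units);
#: depression, loneliness and anxiety dominate, mirroring the importance
#: pattern of the published networks; the depression coefficient is re-set
#: by calibration
_DEFAULT_BETA = {
    "depression": 1.0, "loneliness": 0.6, "anxiety": 0.5,
    "helplessness": 0.1, "insomnia": 0.1, "self_efficacy": -0.1,
    "resilience": -0.12, "qol_physical": -0.08, "qol_psychological": -0.08,
    "qol_relationships": -0.05, "qol_environment": -0.1,
    "exercise": -0.03, "household": 0.0,
}

#: UK only: additive helplessness-latent shift per age band (younger = higher)
_UK_AGE_HELPLESSNESS_SHIFT = [0.5, 0.3, 0.1, -0.1, -0.3, -0.5]

DEPRESSION_CUTOFF = 10  # PHQ-9 total defining the depression flag


# ---------------------------------------------------------------- types

@dataclass
class ScaleSpec:
    """One bounded scale score: support, target moments, driving trait.

    ``reliability`` is the squared correlation between the latent trait and
    the (pre-discretization) score determinant — scores are imperfect
    measurements, as real questionnaires are.
    """

    name: str
    kind: str  # ordinal-sum | count
    lo: int
    hi: int
    target_mean: float
    target_sd: float
    trait: str
    reliability: float = 0.85

    def __post_init__(self):
        if self.lo > self.hi:
            raise ConfigurationError(f"{self.name}: lo > hi")
        if not self.lo <= self.target_mean <= self.hi:
            raise ConfigurationError(f"{self.name}: target mean outside support")
        if self.trait not in TRAITS:
            raise ConfigurationError(f"{self.name}: unknown trait {self.trait}")
        if not 0 < self.reliability <= 1:
            raise ConfigurationError(f"{self.name}: reliability must be in (0,1]")


@dataclass
class OutcomeModel:
    """Logistic model for PHQ-9 item 9 on the standardized latent traits."""

    beta0: float
    beta: dict[str, float]
    severity_split: tuple[float, float, float] = (0.7, 0.2, 0.1)
    phq8_tilt: float = 0.0  # exponential tilt of P(PHQ-8 >= cutoff)

    def beta_vector(self, traits: list[str]) -> np.ndarray:
        return np.array([self.beta.get(t, 0.0) for t in traits])

    def endorsement_prob(self, latents: np.ndarray, traits: list[str]) -> np.ndarray:
        return expit(self.beta0 + latents @ self.beta_vector(traits))


@dataclass
class CalibrationTargets:
    """Printed prevalences: marginal SI, SI among depressed / non-depressed."""

    p_si: float
    p_si_dep: float
    p_si_nondep: float

    def __post_init__(self):
        for p in (self.p_si, self.p_si_dep, self.p_si_nondep):
            if not 0 < p < 1:
                raise ConfigurationError("prevalence targets must lie in (0,1)")
        if not self.p_si_nondep < self.p_si < self.p_si_dep:
            raise ConfigurationError(
                "p_si must lie strictly between p_si_nondep and p_si_dep"
            )

    @property
    def p_dep(self) -> float:
        """Depression rate implied by total probability."""
        return (self.p_si - self.p_si_nondep) / (self.p_si_dep - self.p_si_nondep)


@dataclass
class GeneratorConfig:
    country: str
    n: int
    scale_specs: dict[str, ScaleSpec]
    latent_corr: np.ndarray
    outcome_model: OutcomeModel
    calibration_targets: CalibrationTargets
    demographics: dict = field(default_factory=dict)
    age_helplessness_shift: list[float] | None = None
    seed: int = 0

    def __post_init__(self):
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        if self.n <= 0:
            raise ConfigurationError("n must be positive")
        k = len(TRAITS)
        if self.latent_corr.shape != (k, k):
            raise ConfigurationError(f"latent_corr must be {k}x{k}")
        if not np.allclose(self.latent_corr, self.latent_corr.T):
            raise ConfigurationError("latent_corr must be symmetric")
        if not np.allclose(np.diag(self.latent_corr), 1.0):
            raise ConfigurationError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.latent_corr).min() <= 0:
            raise ConfigurationError("latent_corr must be positive definite")
        for name, probs in self.demographics.items():
            if isinstance(probs, list):
                # printed percentages can round to 99.9/100.1; renormalised at draw
                if abs(sum(probs) - 1.0) > 0.01:
                    raise ConfigurationError(f"demographic probs for {name} not a simplex")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["latent_corr"] = self.latent_corr.round(12).tolist()
        d["outcome_model"]["severity_split"] = list(
            self.outcome_model.severity_split)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["scale_specs"] = {k: ScaleSpec(**v) for k, v in d["scale_specs"].items()}
        om = dict(d["outcome_model"])
        om["severity_split"] = tuple(om["severity_split"])
        d["outcome_model"] = OutcomeModel(**om)
        d["calibration_targets"] = CalibrationTargets(**d["calibration_targets"])
        d["latent_corr"] = np.asarray(d["latent_corr"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------- defaults

def default_latent_corr() -> np.ndarray:
    """Package-default trait correlation matrix.

    Within-block 0.2, depression–anxiety 0.7, depression–loneliness 0.5,
    depression×protective −0.4, other risk×protective −0.2, household size
    uncorrelated.  Verified positive definite (min eigenvalue ≈ 0.12).
    """
    k = len(TRAITS)
    C = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = TRAITS[i], TRAITS[j]
            pair = {a, b}
            if "household" in pair:
                r = 0.0
            elif pair == {"depression", "anxiety"}:
                r = 0.7
            elif pair == {"depression", "loneliness"}:
                r = 0.5
            elif a in _RISK and b in _RISK:
                r = 0.2
            elif a in _PROTECTIVE and b in _PROTECTIVE:
                r = 0.2
            elif "depression" in pair:
                r = -0.4
            else:
                r = -0.2
            C[i, j] = C[j, i] = r
    return C


def default_config(country: str, n: int | None = None) -> GeneratorConfig:
    """Uncalibrated generator config for ``'austria'`` or ``'uk'``."""
    country = country.lower()
    if country not in _SCALE_MOMENTS:
        raise ConfigurationError(f"unknown country {country!r}")
    if n is None:
        n = 1005 if country == "austria" else 1006
    specs = {}
    for col, (m, sd) in _SCALE_MOMENTS[country].items():
        lo, hi = SCALE_SUPPORT[col]
        kind = "count" if col in ("exercise_days", "occupants") else "ordinal-sum"
        specs[col] = ScaleSpec(col, kind, lo, hi, m, sd, SCALE_TRAIT[col])
    p_si, p_si_dep, p_si_nondep = _PREVALENCES[country]
    return GeneratorConfig(
        country=country,
        n=n,
        scale_specs=specs,
        latent_corr=default_latent_corr(),
        outcome_model=OutcomeModel(beta0=-2.8, beta=dict(_DEFAULT_BETA)),
        calibration_targets=CalibrationTargets(p_si, p_si_dep, p_si_nondep),
        demographics=dict(_DEMOGRAPHICS[country]),
        age_helplessness_shift=(
            list(_UK_AGE_HELPLESSNESS_SHIFT) if country == "uk" else None),
    )


# ---------------------------------------------------------------- sampling

def _scale_distribution(spec: ScaleSpec, outcome_model: OutcomeModel
                        ) -> DiscreteScaleDistribution:
    tilt_at, tilt = None, 0.0
    if spec.name == "phq8" and outcome_model.phq8_tilt != 0.0:
        tilt_at, tilt = DEPRESSION_CUTOFF, outcome_model.phq8_tilt
    return DiscreteScaleDistribution(
        spec.target_mean, spec.target_sd, spec.lo, spec.hi,
        tilt_at=tilt_at, tilt=tilt)


def _draw_latents(config: GeneratorConfig, n: int, rng: np.random.Generator,
                  age_idx: np.ndarray | None) -> np.ndarray:
    L = np.linalg.cholesky(config.latent_corr)
    z = rng.standard_normal((n, len(TRAITS))) @ L.T
    if config.age_helplessness_shift is not None:
        if age_idx is None:
            raise ConfigurationError("age draw required for helplessness shift")
        s = np.asarray(config.age_helplessness_shift, dtype=float)
        probs = np.asarray(config.demographics["age_group"], dtype=float)
        probs = probs / probs.sum()
        mu_s = probs @ s
        var_s = probs @ (s - mu_s) ** 2
        j = TRAITS.index("helplessness")
        z[:, j] = (z[:, j] + s[age_idx] - mu_s) / np.sqrt(1.0 + var_s)
    return z


def derive_item9(latents: np.ndarray, outcome_model: OutcomeModel,
                 rng: np.random.Generator) -> np.ndarray:
    """Draw the suicidal-ideation item (0–3) from the logistic outcome model.

    P(item9 >= 1) = logistic(beta0 + beta'z); the severity grade given
    endorsement follows the fixed decreasing split of the model.
    """
    p = outcome_model.endorsement_prob(np.atleast_2d(latents), TRAITS)
    endorsed = rng.random(p.shape[0]) < p
    split = np.asarray(outcome_model.severity_split, dtype=float)
    split = split / split.sum()
    grades = 1 + np.searchsorted(np.cumsum(split), rng.random(p.shape[0]),
                                 side="right").clip(0, 2)
    return np.where(endorsed, grades, 0).astype(np.int64)


def _split_items(totals: np.ndarray, n_items: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Split integer totals into ``n_items`` item scores in 0..3 summing back."""
    base = totals // n_items
    r = totals % n_items
    perm = rng.random((totals.shape[0], n_items)).argsort(axis=1)
    return (base[:, None] + (perm < r[:, None])).astype(np.int64)


def generate_survey(config: GeneratorConfig, seed: int | None = None
                    ) -> pd.DataFrame:
    """Generate one synthetic country sample under ``config``.

    Returns a DataFrame in the fixed CSV schema (one row per respondent,
    complete cases).  Deterministic given the seed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n

    # demographics first (fixed draw order is part of the determinism contract)
    demo = {}
    for col, levels in CATEGORY_LEVELS.items():
        probs = np.asarray(config.demographics[col], dtype=float)
        probs = probs / probs.sum()
        demo[col] = rng.choice(len(levels), size=n, p=probs)
    children = (rng.random(n) < config.demographics["children"]).astype(int)
    illness = (rng.random(n) < config.demographics["illness"]).astype(int)

    z = _draw_latents(config, n, rng, age_idx=demo["age_group"])

    scores = {}
    # canonical order: the rng consumption must not depend on dict ordering
    for col in sorted(config.scale_specs):
        spec = config.scale_specs[col]
        dist = _scale_distribution(spec, config.outcome_model)
        zt = z[:, TRAITS.index(spec.trait)]
        if spec.reliability < 1.0:
            eps = rng.standard_normal(n)
            zt = np.sqrt(spec.reliability) * zt + np.sqrt(1 - spec.reliability) * eps
        scores[col] = dist.from_latent(zt)

    item9 = derive_item9(z, config.outcome_model, rng)
    phq_items = _split_items(scores["phq8"], 8, rng)

    out = {"country": np.full(n, config.country)}
    for col, levels in CATEGORY_LEVELS.items():
        out[col] = np.asarray(levels, dtype=object)[demo[col]]
    out["children"] = children
    out["illness"] = illness
    out["occupants"] = scores["occupants"]
    out["exercise_days"] = scores["exercise_days"]
    for i in range(8):
        out[f"phq_i{i + 1}"] = phq_items[:, i]
    out["phq_i9"] = item9
    for col in ("gad7", "pss_helplessness", "pss_selfefficacy", "isi",
                "loneliness", "cdrisc", "whoqol_physical",
                "whoqol_psychological", "whoqol_relationships",
                "whoqol_environment"):
        out[col] = scores[col]
    return pd.DataFrame(out)[SCHEMA_COLUMNS]


def write_survey_csv(df: pd.DataFrame, path, config: GeneratorConfig | None = None,
                     config_path=None) -> None:
    """Write the sample as CSV (fixed header); optionally the resolved config."""
    df[SCHEMA_COLUMNS].to_csv(path, index=False, lineterminator="\n")
    if config is not None and config_path is not None:
        config.to_yaml(config_path)


# ---------------------------------------------------------------- calibration

def _bisect_on(fun, lo, hi, target, tol, max_iter=60, what=""):
    flo, fhi = fun(lo), fun(hi)
    if not (flo <= target <= fhi):
        raise CalibrationError(
            f"cannot bracket {what}: f({lo})={flo:.4f}, f({hi})={fhi:.4f}, "
            f"target={target:.4f}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = fun(mid)
        if abs(fm - target) <= tol:
            return mid
        if fm < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class _CalibrationSampler:
    """Common-random-number evaluator of the three calibrated prevalences."""

    def __init__(self, config: GeneratorConfig, mc_n: int, seed: int):
        rng = np.random.default_rng(seed)
        age_idx = None
        if config.age_helplessness_shift is not None:
            probs = np.asarray(config.demographics["age_group"], dtype=float)
            age_idx = rng.choice(len(probs), size=mc_n, p=probs / probs.sum())
        self.z = _draw_latents(config, mc_n, rng, age_idx)
        self.u_end = rng.random(mc_n)
        split = np.asarray(config.outcome_model.severity_split, dtype=float)
        split = split / split.sum()
        self.grades = 1 + np.searchsorted(
            np.cumsum(split), rng.random(mc_n), side="right").clip(0, 2)
        self.config = config
        self.spec8 = config.scale_specs["phq8"]
        zdep = self.z[:, TRAITS.index("depression")]
        rel = self.spec8.reliability
        if rel < 1.0:
            zdep = (np.sqrt(rel) * zdep
                    + np.sqrt(1 - rel) * rng.standard_normal(mc_n))
        self.zdep = zdep
        self._phq8_cache: dict[float, np.ndarray] = {}
        self.beta_idx = {t: i for i, t in enumerate(TRAITS)}

    def phq8(self, tilt: float) -> np.ndarray:
        if tilt not in self._phq8_cache:
            dist = DiscreteScaleDistribution(
                self.spec8.target_mean, self.spec8.target_sd,
                self.spec8.lo, self.spec8.hi,
                tilt_at=DEPRESSION_CUTOFF if tilt != 0.0 else None, tilt=tilt)
            self._phq8_cache[tilt] = dist.from_latent(self.zdep)
        return self._phq8_cache[tilt]

    def prevalences(self, tilt: float, beta0: float, beta_dep: float) -> dict:
        om = self.config.outcome_model
        beta = om.beta_vector(TRAITS).copy()
        beta[self.beta_idx["depression"]] = beta_dep
        p = expit(beta0 + self.z @ beta)
        endorsed = self.u_end < p
        item9 = np.where(endorsed, self.grades, 0)
        phq9 = self.phq8(tilt) + item9
        dep = phq9 >= DEPRESSION_CUTOFF
        return {
            "p_si": float(endorsed.mean()),
            "p_si_dep": float(endorsed[dep].mean()) if dep.any() else float("nan"),
            "p_si_nondep": float(endorsed[~dep].mean()) if (~dep).any() else float("nan"),
            "p_dep": float(dep.mean()),
        }


def calibrate_outcome_model(config: GeneratorConfig,
                            targets: CalibrationTargets | None = None,
                            mc_n: int = 200_000, seed: int = 2020,
                            tol: float = 0.003, max_iter: int = 50
                            ) -> GeneratorConfig:
    """Calibrate beta0, the depression coefficient and the PHQ-8 tail tilt.

    Alternating bisection on a fixed Monte-Carlo sample until the marginal SI
    prevalence, the SI prevalence among the depressed and the depression rate
    each match their targets within ``tol``.  Returns a new config; raises
    :class:`CalibrationError` with diagnostics when a bracket fails.
    """
    targets = targets or config.calibration_targets
    sampler = _CalibrationSampler(config, mc_n, seed)
    tilt = config.outcome_model.phq8_tilt
    beta0 = config.outcome_model.beta0
    beta_dep = config.outcome_model.beta["depression"]
    p_dep_target = targets.p_dep

    for _ in range(max_iter):
        got = sampler.prevalences(tilt, beta0, beta_dep)
        if (abs(got["p_dep"] - p_dep_target) <= tol
                and abs(got["p_si"] - targets.p_si) <= tol
                and abs(got["p_si_dep"] - targets.p_si_dep) <= tol):
            break
        tilt = _bisect_on(
            lambda t: sampler.prevalences(t, beta0, beta_dep)["p_dep"],
            -3.0, 3.0, p_dep_target, tol * 0.5, what="PHQ-8 tilt vs p_dep")
        beta0 = _bisect_on(
            lambda b: sampler.prevalences(tilt, b, beta_dep)["p_si"],
            -9.0, 3.0, targets.p_si, tol * 0.5, what="beta0 vs p_si")
        beta_dep = _bisect_on(
            lambda b: sampler.prevalences(tilt, beta0, b)["p_si_dep"],
            0.0, 6.0, targets.p_si_dep, tol * 0.5,
            what="depression coefficient vs p_si_dep")
    else:
        got = sampler.prevalences(tilt, beta0, beta_dep)
        raise CalibrationError(f"calibration did not converge: achieved {got}, "
                               f"targets {dataclasses.asdict(targets)}")

    beta = dict(config.outcome_model.beta)
    beta["depression"] = beta_dep
    om = OutcomeModel(beta0=beta0, beta=beta,
                      severity_split=config.outcome_model.severity_split,
                      phq8_tilt=tilt)
    return dataclasses.replace(config, outcome_model=om,
                               calibration_targets=targets)


def calibrated_config(country: str, n: int | None = None,
                      mc_n: int = 200_000, seed: int = 2020) -> GeneratorConfig:
    """Default config for the country with the outcome model calibrated."""
    return calibrate_outcome_model(default_config(country, n=n),
                                   mc_n=mc_n, seed=seed)


def simulate_prevalences(config: GeneratorConfig, mc_n: int = 100_000,
                         seed: int = 0) -> dict:
    """Monte-Carlo estimate of (p_si, p_si_dep, p_si_nondep, p_dep) under config."""
    sampler = _CalibrationSampler(config, mc_n, seed)
    om = config.outcome_model
    return sampler.prevalences(om.phq8_tilt, om.beta0, om.beta["depression"])
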