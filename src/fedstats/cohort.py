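"""Deterministic synthetic two-site cohort generator with ground truth.

The study's raw patient tables are protected by privacy law, so every other
module here is exercised against synthetic per-site CSVs whose *marginal*
structure matches the published cohort description: 60% male, ECOG 0/1/2 =
18/22/8 of 48, left/right/bilateral adrenal laterality 24/18/6, 21%/79%
3-/5-fraction schemes with the printed dose ranges, lognormal gross tumor
volumes around a 21 cm^3 median, exponential overall survival with a
19-month target median (ECOG-2 patients on a proportionally higher hazard),
and administrative censoring from uniform accrual over a 27-month window.

Joint structure between factors is invented (the study publishes only
marginals): factors are independent except the ECOG -> hazard link and the
arithmetic identities (BED10 from the sampled scheme, body-mass index from
height and weight, and so on).  The generating parameters are retrievable
via :func:`true_params` for parameter-recovery tests.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import optimize

from .clinical import DoseScheme, bed
from .dictionary import default_dictionary


class CohortConfigError(ValueError):
    """Inconsistent generator configuration (e.g. marginals not summing to 1)."""


def _probs(*p: float) -> tuple[float, ...]:
    return tuple(float(x) for x in p)


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults encode the published marginals."""

    n_per_site: int = 24
    male_fraction: float = 0.60
    ecog_probs: tuple = _probs(18 / 48, 22 / 48, 8 / 48)
    laterality_probs: tuple = _probs(24 / 48, 18 / 48, 6 / 48)
    timing_probs: tuple = _probs(23 / 48, 13 / 48, 8 / 48, 4 / 48)
    pattern_probs: tuple = _probs(9 / 48, 26 / 48, 12 / 48, 1 / 48)
    chemo_probs: tuple = _probs(23 / 48, 14 / 48, 9 / 48, 2 / 48, 0.0)
    immuno_probs: tuple = _probs(29 / 48, 13 / 48, 2 / 48, 3 / 48, 1 / 48)
    primary_probs: tuple = _probs(29 / 46, 4 / 46, 4 / 46, 3 / 46, 2 / 46, 4 / 46)
    toxicity_probs: tuple = _probs(35 / 48, 8 / 48, 2 / 48, 1 / 48, 2 / 48)
    motion_probs: tuple = _probs(39 / 48, 7 / 48, 2 / 48)
    fractionation_3fx: float = 0.21
    dose_range_3fx_gy: tuple = (24.0, 45.0)
    dose_range_5fx_gy: tuple = (30.0, 50.0)
    dose_grid_gy: float = 0.5
    gtv_median_cm3: float = 21.0
    gtv_log_sigma: float = 1.0
    median_survival_months: float = 19.0
    ecog2_hazard_multiplier: float = 2.2
    max_follow_up_months: float = 27.0
    adapted_fraction_prob: float = 0.71
    age_mean: float = 65.0
    age_sd: float = 12.0
    age_range: tuple = (38.0, 91.0)

    def validate(self) -> None:
        if self.n_per_site <= 0:
            raise CohortConfigError("n_per_site must be positive")
        for name in ("ecog_probs", "laterality_probs", "timing_probs",
                     "pattern_probs", "chemo_probs", "immuno_probs",
                     "primary_probs", "toxicity_probs", "motion_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise CohortConfigError(f"{name} must be a probability vector")
        if not 0 <= self.male_fraction <= 1:
            raise CohortConfigError("male_fraction must be a probability")
        if not 0 <= self.fractionation_3fx <= 1:
            raise CohortConfigError("fractionation_3fx must be a probability")
        if self.median_survival_months <= 0 or self.max_follow_up_months <= 0:
            raise CohortConfigError("survival horizon parameters must be positive")
        if self.ecog2_hazard_multiplier <= 0:
            raise CohortConfigError("hazard multiplier must be positive")

    def key(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class GroundTruth:
    """The parameters a generated cohort was actually sampled from."""

    median_survival_months: float
    baseline_hazard: float
    ecog2_hazard: float
    ecog2_hazard_multiplier: float
    male_fraction: float
    ecog_probs: tuple
    max_follow_up_months: float
    n: int
    seed: int
    site_label: str


_REGISTRY: dict[tuple[str, int], GroundTruth] = {}


def baseline_hazard(config: CohortConfig) -> float:
    """Hazard h such that the ECOG-mixture survival has the target median.

    The population survival is p01 e^{-h t} + p2 e^{-mult h t}; h is found by
    root finding so S(median) = 1/2 holds exactly for the configured median.
    """
    p2 = config.ecog_probs[2]
    p01 = 1.0 - p2
    m = config.median_survival_months
    mult = config.ecog2_hazard_multiplier

    def gap(h: float) -> float:
        return p01 * math.exp(-h * m) + p2 * math.exp(-mult * h * m) - 0.5

    lo, hi = 1e-9, 10.0 / m
    return float(optimize.brentq(gap, lo, hi, xtol=1e-14))


def _snap(x: np.ndarray, grid: float) -> np.ndarray:
    return np.round(x / grid) * grid


def generate_site(config: CohortConfig, seed: int, site_label: str
                  ) -> tuple[str, GroundTruth]:
    """One site's CSV (against the default dictionary) plus ground truth.

    Deterministic: the same (config, seed) yields byte-identical CSV text.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_per_site
    d = default_dictionary()

    def cat(name: str, probs) -> np.ndarray:
        labels = d[name].categories
        if len(labels) != len(probs):
            raise CohortConfigError(
                f"{name}: {len(probs)} probabilities for {len(labels)} categories")
        return rng.choice(len(labels), size=n, p=np.asarray(probs) / sum(probs))

    cols: dict[str, np.ndarray] = {}
    gender = (rng.random(n) >= config.male_fraction).astype(int)  # 0 male
    ecog = cat("ecog_status", config.ecog_probs)
    cols["gender"] = gender
    cols["ecog_status"] = ecog
    cols["laterality"] = cat("laterality", config.laterality_probs)
    cols["timing_metastases"] = cat("timing_metastases", config.timing_probs)
    cols["metastatic_pattern"] = cat("metastatic_pattern", config.pattern_probs)
    chemo = cat("chemotherapy_timing", config.chemo_probs)
    immuno = cat("immunotherapy_timing", config.immuno_probs)
    cols["chemotherapy_timing"] = chemo
    cols["immunotherapy_timing"] = immuno
    cols["primary_site"] = cat("primary_site", config.primary_probs)

    three_fx = rng.random(n) < config.fractionation_3fx
    n_fx = np.where(three_fx, 3, 5)
    lo3, hi3 = config.dose_range_3fx_gy
    lo5, hi5 = config.dose_range_5fx_gy
    dose = np.where(three_fx,
                    rng.uniform(lo3, hi3, n),
                    rng.uniform(lo5, hi5, n))
    dose = _snap(dose, config.dose_grid_gy)
    dose = np.clip(dose, np.where(three_fx, lo3, lo5), np.where(three_fx, hi3, hi5))
    bed10 = np.array([
        float(bed(DoseScheme(float(D), int(k)))) for D, k in zip(dose, n_fx)
    ])
    cols["fractionation_group"] = np.where(three_fx, 0, 1)
    cols["motion_management"] = cat("motion_management", config.motion_probs)

    tox = cat("toxicity_type", config.toxicity_probs)
    cols["toxicity_type"] = tox
    has_tox = (tox != 0) & (tox != 4)  # neither "none" nor "not_reported"
    grade = np.where(has_tox, rng.choice([1, 2], size=n, p=[6 / 11, 5 / 11]), 0)
    cols["toxicity_grade"] = grade

    lc = cat("local_control", _probs(10 / 48, 13 / 48, 19 / 48, 4 / 48, 2 / 48))
    cols["local_control"] = lc
    cols["complete_remission"] = (lc == 0).astype(int)
    cols["bed_group"] = (bed10 >= 80.0).astype(int)
    cols["chemotherapy_any"] = (chemo != 0).astype(int)
    cols["immunotherapy_any"] = (immuno != 0).astype(int)

    adapted = rng.binomial(n_fx, config.adapted_fraction_prob)
    cols["adapted_any"] = (adapted > 0).astype(int)
    cols["primary_controlled"] = rng.integers(0, 2, n)

    # survival: exponential per ECOG stratum, administrative censoring from
    # uniform accrual over the follow-up window
    h0 = baseline_hazard(config)
    hazards = np.where(ecog == 2, config.ecog2_hazard_multiplier * h0, h0)
    t_event = rng.exponential(1.0 / hazards)
    accrual = rng.uniform(0.0, config.max_follow_up_months, n)
    t_censor = config.max_follow_up_months - accrual
    follow_up = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    cols["event_death"] = event

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), *config.age_range)
    gtv = np.exp(rng.normal(math.log(config.gtv_median_cm3),
                            config.gtv_log_sigma, n))
    ptv = gtv * rng.uniform(1.5, 2.0, n) + rng.uniform(2.0, 5.0, n)
    margin = rng.choice([3.0, 4.0, 5.0, 6.0], size=n, p=[0.7, 0.15, 0.1, 0.05])
    dmax = dose * np.where(three_fx, rng.uniform(1.3, 1.6, n),
                           rng.uniform(1.1, 1.35, n))
    height = np.where(gender == 0, rng.normal(176, 7, n), rng.normal(164, 6, n))
    weight = np.where(gender == 0, rng.normal(80, 12, n), rng.normal(68, 11, n))
    weight = np.clip(weight, 40, 150)

    metrics = {
        "age": age,
        "follow_up": follow_up,
        "gtv_cm3": gtv,
        "ptv_cm3": ptv,
        "ptv_margin_mm": margin,
        "n_fractions": n_fx.astype(float),
        "prescription_dose_gy": dose,
        "dose_per_fraction_gy": dose / n_fx,
        "bed10_gy": bed10,
        "ptvopt_dmax_gy": dmax,
        "conformity_index": np.clip(rng.normal(0.98, 0.15, n), 0.4, 1.4),
        "homogeneity_index": np.clip(rng.normal(1.25, 0.15, n), 1.02, 1.9),
        "adapted_fractions_n": adapted.astype(float),
        "adapted_fraction_ratio": adapted / n_fx,
        "height_cm": height,
        "weight_kg": weight,
        "bmi": weight / (height / 100.0) ** 2,
        "karnofsky_index": np.clip(92 - 12 * ecog + rng.normal(0, 4, n), 40, 100),
        "creatinine_mg_dl": np.clip(rng.normal(0.95, 0.2, n), 0.4, 3.0),
        "hemoglobin_g_dl": np.clip(rng.normal(13.0, 1.6, n), 7.0, 18.0),
        "treatment_duration_days": n_fx * 2 + rng.uniform(2.0, 9.0, n),
        "time_diagnosis_to_rt_months": np.exp(rng.normal(2.3, 0.8, n)),
        "gtv_to_ptv_ratio": gtv / ptv,
        "accrual_month": accrual,
    }

    frame = {}
    for spec in d.columns:
        if spec.kind == "categorical":
            codes = cols[spec.name]
            frame[spec.name] = [spec.categories[int(c)] for c in codes]
        else:
            frame[spec.name] = np.round(metrics[spec.name], 4)
    df = pd.DataFrame(frame, columns=d.names)
    csv_text = df.to_csv(index=False, float_format="%.4f")

    truth = GroundTruth(
        median_survival_months=config.median_survival_months,
        baseline_hazard=h0,
        ecog2_hazard=h0 * config.ecog2_hazard_multiplier,
        ecog2_hazard_multiplier=config.ecog2_hazard_multiplier,
        male_fraction=config.male_fraction,
        ecog_probs=tuple(config.ecog_probs),
        max_follow_up_months=config.max_follow_up_months,
        n=n,
        seed=seed,
        site_label=site_label,
    )
    _REGISTRY[(config.key(), seed)] = truth
    return csv_text, truth


def true_params(config: CohortConfig, seed: int) -> GroundTruth:
    """Ground truth of a previously generated cohort (KeyError if unknown)."""
    try:
        return _REGISTRY[(config.key(), seed)]
    except KeyError:
        raise KeyError(
            f"no cohort was generated with this configuration and seed {seed}"
        ) from None
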