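"""Synthetic capnography cohort generator.

Generates complete subject records — demographics, single-breath CO2/flow
traces, capnogram features and spirometry (FEV1, FVC) — with the
marginal statistics of the study population this package targets:
~53 % male, age 56 +/- 14 y (truncated to 17-70), height 166 +/- 9 cm,
weight 69 +/- 14 kg, capnogram features centred on C12 2.49 mmHg,
V12 276 mL, V23 757 mL, S2 74.6 mmHg/L, S3 5.44 mmHg/L, Angle23 ~168 deg,
and spirometry FEV1 2.53 L / FVC 3.49 L with ~35 % airflow obstruction
(FEV1/FVC < 0.7).

The generative structure is a package fixture, calibrated to those
marginals only:

* FVC follows a linear model in height, age and sex plus Gaussian noise;
* FEV1 = ratio * FVC with the ratio drawn from a class-conditional
  truncated normal on either side of the 0.7 cutoff (strict "<");
* the CO2-vs-volume curve is an idealized three-phase capnogram — a flat
  phase I plateau at C12, a linear phase II rise with slope S2, and a
  linear phase III plateau with slope S3 — sampled along a ramp-then-
  exponential-decay expiratory flow profile whose peak scales with FEV1
  and whose integral equals the expired volume (itself a fraction of
  FVC), so the raw time series carries genuine spirometric signal;
* obstruction shifts: S3 (and hence S3/S2 and Angle23) scaled up, and a
  larger expired-volume fraction (air trapping -> larger V3).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .capnogram import CapnoFeatures, CapnogramTrace, integrate_volume

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "sample_demographics",
    "simulate_spirometry",
    "simulate_capnogram",
    "generate_cohort",
    "cohort_to_frame",
]


def _trunc_normal(rng, mean, sd, lower=-np.inf, upper=np.inf, size=None):
    """Truncated-normal draw; degenerates to the (clipped) mean at sd=0."""
    if sd == 0:
        val = np.clip(mean, lower, upper)
        return val if size is None else np.full(size, val)
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the target population's marginals; SDs may be set
    to 0 for degenerate (all-identical) cohorts in tests.
    """

    n: int = 500
    seed: int = 0

    # demographics
    male_fraction: float = 0.531
    age_mean: float = 56.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (17.0, 70.0)
    height_mean: float = 166.0
    height_sd: float = 9.0
    weight_mean: float = 69.0
    weight_sd: float = 14.0

    # spirometry: FVC = b0 + bh*height + ba*age + bs*male + N(0, sigma)
    obstruction_prevalence: float = 0.35
    fvc_intercept: float = -6.45
    fvc_height_coef: float = 0.065    # L/cm
    fvc_age_coef: float = -0.022      # L/y
    fvc_male_coef: float = 0.6        # L
    fvc_sigma: float = 0.35           # L
    fvc_floor: float = 1.0            # L
    ratio_normal: tuple[float, float] = (0.80, 0.05)      # truncated to (0.70, 0.95]
    ratio_obstructed: tuple[float, float] = (0.60, 0.08)  # truncated to (0.30, 0.70)

    # capnogram feature marginals (mean, sd)
    c12: tuple[float, float] = (2.49, 0.80)
    v12: tuple[float, float] = (276.0, 58.0)
    v23: tuple[float, float] = (757.0, 157.0)
    s2: tuple[float, float] = (74.63, 25.19)
    # class-conditional S3 base; the obstructed class is scaled by
    # s3_obstructed_factor, and the base is calibrated so the mixture
    # mean lands on 5.44 mmHg/L at the default prevalence.
    s3_base: tuple[float, float] = (4.11, 2.55)
    s3_obstructed_factor: float = 1.6
    # expired volume as a fraction of FVC; obstructed scaled up
    ve_fraction: tuple[float, float] = (0.78, 0.05)
    ve_obstructed_factor: float = 1.12

    # flow profile / trace synthesis
    fs: float = 200.0
    min_samples: int = 4096
    pef_per_fev1: float = 0.45        # peak expiratory flow, L/s per L FEV1
    ramp_time: float = 0.3            # s to reach peak flow
    noise_sigma: float = 0.3          # mmHg, additive Gaussian on CO2

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if not 0.0 <= self.obstruction_prevalence <= 1.0:
            raise ValueError("obstruction_prevalence must be in [0, 1]")
        for name in ("age_sd", "height_sd", "weight_sd", "fvc_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SubjectRecord:
    """One synthetic subject: demographics, breath trace, features, spirometry."""

    id: str
    sex: str                  # "M" or "F"
    age: float                # years
    height: float             # cm
    weight: float             # kg
    bmi: float                # kg/m^2
    features: CapnoFeatures   # generator-truth feature values
    trace: CapnogramTrace
    fev1: float               # L
    fvc: float                # L
    obstructed: bool          # FEV1/FVC < 0.7 (strict)

    @property
    def sequence(self) -> np.ndarray:
        """Raw CO2 series (mmHg) at the trace sampling rate."""
        return self.trace.co2

    @property
    def male(self) -> int:
        return int(self.sex == "M")


def sample_demographics(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Draw sex, age, height, weight for one subject; BMI is computed."""
    sex = "M" if rng.random() < config.male_fraction else "F"
    age = float(
        _trunc_normal(rng, config.age_mean, config.age_sd, *config.age_range)
    )
    height = float(
        _trunc_normal(rng, config.height_mean, config.height_sd, 140.0, 200.0)
    )
    weight = float(_trunc_normal(rng, config.weight_mean, config.weight_sd, 35.0, 140.0))
    bmi = weight / (height / 100.0) ** 2
    return {"sex": sex, "age": age, "height": height, "weight": weight, "bmi": bmi}


def simulate_spirometry(
    demographics: dict, obstructed: bool, config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw (FEV1, FVC) in liters for one subject.

    FVC follows the linear structural model; FEV1 = ratio * FVC with the
    ratio drawn on the appropriate side of the 0.7 cutoff (strict "<"
    for obstruction, so a ratio of exactly 0.7 is non-obstructed).
    """
    male = 1.0 if demographics["sex"] == "M" else 0.0
    fvc = (
        config.fvc_intercept
        + config.fvc_height_coef * demographics["height"]
        + config.fvc_age_coef * demographics["age"]
        + config.fvc_male_coef * male
        + (rng.normal(0.0, config.fvc_sigma) if config.fvc_sigma > 0 else 0.0)
    )
    fvc = max(fvc, config.fvc_floor)
    if obstructed:
        mu, sd = config.ratio_obstructed
        ratio = float(_trunc_normal(rng, mu, sd, 0.30, 0.70 - 1e-9))
    else:
        mu, sd = config.ratio_normal
        ratio = float(_trunc_normal(rng, mu, sd, 0.70 + 1e-9, 0.95))
    return ratio * fvc, fvc


def _draw_feature_set(
    fvc: float, obstructed: bool, config: CohortConfig, rng: np.random.Generator
) -> dict:
    """Draw a mutually consistent set of capnogram curve parameters.

    V23 is redrawn (up to 100 attempts) until it clears V12; the expired
    volume VE tracks FVC and is adjusted so the plateau and baseline
    fitting windows of the extractor stay inside their phases, keeping
    the feature round trip exact at zero noise.
    """
    s2 = float(_trunc_normal(rng, *config.s2, 30.0, 160.0))
    mu3, sd3 = config.s3_base
    if obstructed:
        mu3, sd3 = mu3 * config.s3_obstructed_factor, sd3 * config.s3_obstructed_factor
    s3 = float(_trunc_normal(rng, mu3, sd3, 0.5, 0.4 * s2))
    c12 = float(_trunc_normal(rng, *config.c12, 0.3, 8.0))
    v12 = float(_trunc_normal(rng, *config.v12, 120.0, 520.0))
    mu_v23, sd_v23 = config.v23
    for attempt in range(100):
        v23 = float(rng.normal(mu_v23, sd_v23)) if sd_v23 > 0 else mu_v23
        if v23 > v12 + 120.0:
            break
    else:
        raise RuntimeError("could not draw V23 > V12 + 120 mL in 100 attempts")

    mu_ve, sd_ve = config.ve_fraction
    ve_frac = float(_trunc_normal(rng, mu_ve, sd_ve, 0.55, 0.92))
    if obstructed:
        ve_frac = min(ve_frac * config.ve_obstructed_factor, 0.95)
    ve = ve_frac * fvc * 1000.0                 # mL
    ve = max(ve, v23 / 0.55 + 50.0)             # keep V23 <= 55 % of VE
    v12 = max(v12, 0.056 * ve)                  # keep baseline window inside phase I
    if v23 < v12 + 100.0:
        v23 = v12 + 120.0
    c23 = c12 + s2 * (v23 - v12) / 1000.0
    return {
        "c12": c12, "v12": v12, "v23": v23, "ve": ve,
        "s2": s2, "s3": s3, "c23": c23,
    }


def _co2_curve(volume_ml, p) -> np.ndarray:
    """Idealized three-phase CO2-vs-volume curve (volumes in mL)."""
    v = np.asarray(volume_ml, dtype=float)
    phase2 = p["c12"] + p["s2"] * (v - p["v12"]) / 1000.0
    phase3 = p["c23"] + p["s3"] * (v - p["v23"]) / 1000.0
    return np.where(v <= p["v12"], p["c12"], np.where(v <= p["v23"], phase2, phase3))


def simulate_capnogram(
    fev1: float, fvc: float, obstructed: bool, config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[CapnoFeatures, CapnogramTrace]:
    """Synthesize one breath: feature truth plus the sampled CO2/flow trace.

    The flow profile ramps to a peak proportional to FEV1, then decays
    exponentially with the time constant that makes the integrated
    volume equal the drawn expired volume.  The trace is sampled at
    ``config.fs`` for at least ``config.min_samples`` points.
    """
    p = _draw_feature_set(fvc, obstructed, config, rng)
    ve_l = p["ve"] / 1000.0
    pef = max(config.pef_per_fev1 * fev1, ve_l / 3.5)   # L/s; bounded emptying time
    t_r = config.ramp_time
    tau = ve_l / pef - t_r / 2.0                        # ramp area + pef*tau = VE
    tau = max(tau, 0.2)

    n = max(config.min_samples, int(np.ceil((t_r + 8.0 * tau) * config.fs)) + 1)
    t = np.arange(n) / config.fs
    flow = np.where(
        t < t_r, pef * t / t_r, pef * np.exp(-(t - t_r) / np.maximum(tau, 1e-9))
    )
    volume = integrate_volume(flow, config.fs)
    co2 = _co2_curve(volume, p)
    if config.noise_sigma > 0:
        co2 = co2 + rng.normal(0.0, config.noise_sigma, size=n)
    co2 = np.maximum(co2, 0.0)

    v2 = p["v23"] - p["v12"]
    v3 = max(float(volume[-1]) - p["v23"], 0.0)
    angle = 180.0 - np.degrees(np.arctan(p["s2"])) + np.degrees(np.arctan(p["s3"]))
    features = CapnoFeatures(
        C12=p["c12"], C23=p["c23"], V12=p["v12"], V23=p["v23"], V2=v2, V3=v3,
        S2=p["s2"], S3=p["s3"], S3_over_S2=p["s3"] / p["s2"], Angle23=float(angle),
    )
    trace = CapnogramTrace(co2=co2, flow=flow, fs=config.fs, volume=volume)
    return features, trace


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate ``config.n`` complete subject records, deterministically.

    Each subject gets an independent child RNG spawned from the seed, so
    records are independent and the cohort is reproducible byte-for-byte
    under the same configuration.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n)
    records = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        demo = sample_demographics(config, rng)
        obstructed = bool(rng.random() < config.obstruction_prevalence)
        fev1, fvc = simulate_spirometry(demo, obstructed, config, rng)
        features, trace = simulate_capnogram(fev1, fvc, obstructed, config, rng)
        records.append(
            SubjectRecord(
                id=f"S{i:04d}", sex=demo["sex"], age=demo["age"],
                height=demo["height"], weight=demo["weight"], bmi=demo["bmi"],
                features=features, trace=trace, fev1=fev1, fvc=fvc,
                obstructed=obstructed,
            )
        )
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate a cohort: demographics + features + spirometry, one row each."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.id, "sex": r.sex, "age_y": r.age,
            "height_cm": r.height, "weight_kg": r.weight, "bmi": r.bmi,
        }
        row.update(dict(zip(
            ("C12", "C23", "V12", "V23", "V2", "V3", "S2", "S3",
             "S3_over_S2", "Angle23"),
            r.features.as_array(),
        )))
        row.update({"fev1_l": r.fev1, "fvc_l": r.fvc, "obstructed": int(r.obstructed)})
        rows.append(row)
    return pd.DataFrame(rows)
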