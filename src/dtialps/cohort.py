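"""Synthetic cohorts with known (planted) ALPS effect structure.

Emulates a community aging cohort: n = 142, ages truncated-normal above 50,
vascular risk factors at the observed prevalences, a 0-2 venous-disruption
(deep-medullary-vein, DMV) score, small-vessel-disease covariates, and an
ALPS outcome generated from four planted standardized effects — age, sex
(male = 1), hypertension, DMV score — plus independent Gaussian residual.
All remaining covariates carry zero planted effect; they exist to exercise
variable selection.

Generative links
----------------
Hypertension is Bernoulli with a logistic link on standardized age, and the
DMV score follows an age-linked ordered-logit, both with a shared slope.
That slope is the single calibration knob: with independent predictors the
four planted betas cap the population R-squared at
``beta' beta = 0.2216``, so the age links are tightened until
``beta' R beta`` (R = population predictor correlation matrix) reaches the
configured target while every marginal (prevalence, score distribution)
stays fixed.  The calibration integrals are 1-D quadratures over the
truncated age distribution — fully deterministic.

With the total ALPS variance held at the configured marginal variance, the
population R-squared of the four-predictor model *is* ``beta' R beta``, and
the residual SD is ``alps_sd * sqrt(1 - R2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .io import COHORT_SCHEMA_COLUMNS, validate_cohort

__all__ = [
    "CohortSpec",
    "CalibrationError",
    "default_cohort_spec",
    "calibrate_spec",
    "sample_cohort",
]


class CalibrationError(ValueError):
    """The requested R-squared is unreachable with the configured structure."""


@dataclass(frozen=True)
class CohortSpec:
    """All marginals, planted effects and calibrated link parameters.

    Calibrated fields (``age_mu_pre``, ``link_slope``, ``ht_intercept``,
    ``dmv_cutpoints``, ``resid_sd``, ``achieved_r2``) are ``None`` until
    :func:`calibrate_spec` fills them in.
    """

    n_subjects: int = 142
    # age: truncated normal, left-truncated; the pre-truncation mean is
    # calibrated so the post-truncation mean hits age_mean
    age_mean: float = 60.8
    age_sd: float = 7.0
    age_min: float = 50.0
    # binary prevalences
    p_female: float = 0.556
    p_hypertension: float = 0.394
    p_hyperlipemia: float = 0.162
    p_diabetes: float = 14.0 / 142.0
    p_smoker: float = 0.282
    # sleep score
    psqi_mean: float = 5.4
    psqi_sd: float = 3.9
    # venous score marginal P(0), P(1), P(2)
    dmv_marginal: tuple[float, float, float] = (0.50, 0.35, 0.15)
    # planted standardized effects (male = 1)
    beta_age: float = -0.284
    beta_sex: float = -0.243
    beta_hypertension: float = -0.189
    beta_dmv: float = -0.215
    # ALPS marginal and model target
    alps_mean: float = 1.49
    alps_sd: float = 0.17
    target_r2: float = 0.319
    # left/right split: half-difference SD around the bilateral mean
    alps_lr_half_diff_sd: float = 0.05
    # nuisance covariates (zero planted effect)
    icv_mean_ml: float = 1450.0
    icv_sd_ml: float = 130.0
    brain_to_icv_mean: float = 0.78
    brain_to_icv_sd: float = 0.04
    wmh_ml_median: float = 1.5
    wmh_ml_log_sd: float = 0.87
    bgpvs_probs: tuple[float, ...] = (0.15, 0.65, 0.15, 0.04, 0.01)
    wmpvs_probs: tuple[float, ...] = (0.10, 0.40, 0.40, 0.08, 0.02)
    lacune_rate: float = 0.0806
    microbleed_rate: float = 0.1118
    wmh_overlap_zero_prob: float = 0.70
    wmh_overlap_mean_mm3: float = 16.0
    # calibrated parameters
    age_mu_pre: float | None = None
    link_slope: float | None = None
    ht_intercept: float | None = None
    dmv_cutpoints: tuple[float, float] | None = None
    resid_sd: float | None = None
    achieved_r2: float | None = None

    def __post_init__(self) -> None:
        for name in ("p_female", "p_hypertension", "p_hyperlipemia", "p_diabetes", "p_smoker"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.age_sd <= 0 or self.psqi_sd <= 0 or self.alps_sd <= 0:
            raise ValueError("all SDs must be > 0")
        if not 0.0 < self.target_r2 < 1.0:
            raise ValueError(f"target_r2 must be in (0, 1), got {self.target_r2}")
        if abs(sum(self.dmv_marginal) - 1.0) > 1e-9 or any(p <= 0 for p in self.dmv_marginal):
            raise ValueError(f"dmv_marginal must be positive and sum to 1, got {self.dmv_marginal}")
        if self.resid_sd is not None and self.resid_sd <= 0:
            raise ValueError("calibrated residual SD must be > 0")

    @property
    def is_calibrated(self) -> bool:
        return self.resid_sd is not None

    @property
    def betas(self) -> dict[str, float]:
        return {
            "age": self.beta_age,
            "sex": self.beta_sex,
            "hypertension": self.beta_hypertension,
            "dmv_score": self.beta_dmv,
        }


def _truncnorm_args(mu: float, sd: float, lo: float) -> tuple[float, float]:
    return (lo - mu) / sd, np.inf


def _age_dist(spec: CohortSpec, mu_pre: float):
    a, b = _truncnorm_args(mu_pre, spec.age_sd, spec.age_min)
    return truncnorm(a, b, loc=mu_pre, scale=spec.age_sd)


def _calibrate_age_mu(spec: CohortSpec) -> float:
    """Pre-truncation mean such that the post-truncation mean is age_mean."""

    def gap(mu):
        return _age_dist(spec, mu).mean() - spec.age_mean

    return float(brentq(gap, spec.age_mean - 6 * spec.age_sd, spec.age_mean + spec.age_sd))


def _dmv_moments(marginal) -> tuple[float, float]:
    k = np.arange(len(marginal))
    p = np.asarray(marginal)
    mean = float(k @ p)
    var = float((k**2) @ p - mean**2)
    return mean, var


class _LinkSystem:
    """Quadrature helpers over the (truncated) age distribution."""

    def __init__(self, spec: CohortSpec, mu_pre: float):
        self.spec = spec
        self.dist = _age_dist(spec, mu_pre)
        self.z_mean = spec.age_mean
        self.z_sd = float(self.dist.std())
        self.lo = spec.age_min
        self.hi = float(mu_pre + 10 * spec.age_sd)

    def expect(self, fn) -> float:
        val, _ = quad(
            lambda a: fn((a - self.z_mean) / self.z_sd) * self.dist.pdf(a),
            self.lo,
            self.hi,
            limit=200,
        )
        return float(val)

    def ht_intercept(self, slope: float) -> float:
        target = self.spec.p_hypertension

        def gap(b0):
            return self.expect(lambda z: expit(b0 + slope * z)) - target

        return float(brentq(gap, -30.0, 30.0))

    def dmv_cutpoints(self, slope: float) -> tuple[float, float]:
        p0, p1, _ = self.spec.dmv_marginal

        def cut(target_cum):
            def gap(c):
                return self.expect(lambda z: expit(c - slope * z)) - target_cum

            return float(brentq(gap, -30.0, 30.0))

        return cut(p0), cut(p0 + p1)

    def dmv_cond_mean(self, z, slope: float, cuts) -> float:
        c0, c1 = cuts
        le0 = expit(c0 - slope * z)
        le1 = expit(c1 - slope * z)
        return (le1 - le0) + 2.0 * (1.0 - le1)

    def correlations(self, slope: float) -> dict[str, float]:
        """rho(age, ht), rho(age, dmv), rho(ht, dmv) under the links."""
        spec = self.spec
        b0 = self.ht_intercept(slope)
        cuts = self.dmv_cutpoints(slope)
        p_ht = spec.p_hypertension
        sd_ht = np.sqrt(p_ht * (1 - p_ht))
        dmv_mean, dmv_var = _dmv_moments(spec.dmv_marginal)
        sd_dmv = np.sqrt(dmv_var)
        cov_ah = self.expect(lambda z: z * expit(b0 + slope * z))
        cov_ad = self.expect(lambda z: z * self.dmv_cond_mean(z, slope, cuts))
        # ht and dmv are conditionally independent given age
        e_prod = self.expect(lambda z: expit(b0 + slope * z) * self.dmv_cond_mean(z, slope, cuts))
        cov_hd = e_prod - p_ht * dmv_mean
        return {
            "age_ht": cov_ah / sd_ht,
            "age_dmv": cov_ad / sd_dmv,
            "ht_dmv": cov_hd / (sd_ht * sd_dmv),
            "_ht_intercept": b0,
            "_cuts": cuts,
        }


def _beta_r_beta(spec: CohortSpec, rho: dict[str, float]) -> float:
    b_a, b_s, b_h, b_d = spec.beta_age, spec.beta_sex, spec.beta_hypertension, spec.beta_dmv
    base = b_a**2 + b_s**2 + b_h**2 + b_d**2
    cross = 2 * (
        b_a * b_h * rho["age_ht"] + b_a * b_d * rho["age_dmv"] + b_h * b_d * rho["ht_dmv"]
    )
    return base + cross


def calibrate_spec(spec: CohortSpec) -> CohortSpec:
    """Complete a spec: age-mean shift, link slope, cutpoints, residual SD.

    Finds the shared logistic / ordered-logit slope on standardized age such
    that the population ``beta' R beta`` of the four planted predictors
    equals ``target_r2``, then sets
    ``resid_sd = alps_sd * sqrt(1 - target_r2)``.  Raises
    :class:`CalibrationError` when the target is unreachable, saying which
    correlation to raise.
    """
    mu_pre = _calibrate_age_mu(spec)
    sys = _LinkSystem(spec, mu_pre)

    def achieved(slope: float) -> float:
        return _beta_r_beta(spec, sys.correlations(slope))

    at_zero = achieved(0.0)
    slope_hi = 8.0
    at_hi = achieved(slope_hi)
    target = spec.target_r2
    if target < at_zero - 1e-9:
        raise CalibrationError(
            f"target R2 {target:.4f} is below the independent-predictor floor "
            f"beta'beta = {at_zero:.4f}; lower the planted betas or allow "
            "negative predictor correlations"
        )
    if target > at_hi + 1e-9:
        raise CalibrationError(
            f"target R2 {target:.4f} exceeds the maximum {at_hi:.4f} reachable by "
            "tightening the age-hypertension and age-DMV links; raise those "
            "correlations (e.g. stronger betas or wider age range)"
        )
    if abs(target - at_zero) <= 1e-9:
        slope = 0.0
    else:
        slope = float(brentq(lambda s: achieved(s) - target, 0.0, slope_hi, xtol=1e-8))
    rho = sys.correlations(slope)
    achieved_r2 = _beta_r_beta(spec, rho)
    resid_var = spec.alps_sd**2 * (1.0 - target)
    if resid_var <= 0:
        raise CalibrationError("implied residual variance is non-positive")
    return replace(
        spec,
        age_mu_pre=mu_pre,
        link_slope=slope,
        ht_intercept=rho["_ht_intercept"],
        dmv_cutpoints=tuple(rho["_cuts"]),
        resid_sd=float(np.sqrt(resid_var)),
        achieved_r2=float(achieved_r2),
    )


@lru_cache(maxsize=1)
def _default_calibrated() -> CohortSpec:
    return calibrate_spec(CohortSpec())


def default_cohort_spec() -> CohortSpec:
    """The default, fully calibrated cohort spec (n = 142, planted
    standardized effects age -0.284, sex -0.243, hypertension -0.189,
    DMV -0.215, model R-squared target 0.319)."""
    return _default_calibrated()


def sample_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort table from a calibrated spec; deterministic per seed.

    The ALPS outcome is built from *population*-standardized predictors, so
    the planted betas are exact population quantities rather than
    sample-dependent ones.  Left/right hemispheric ALPS are the bilateral
    mean plus/minus an independent Gaussian half-difference.
    """
    if not spec.is_calibrated:
        spec = calibrate_spec(spec)
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    dist = _age_dist(spec, spec.age_mu_pre)
    age = dist.rvs(size=n, random_state=rng)
    z_age = (age - spec.age_mean) / float(dist.std())

    male = (rng.random(n) < (1.0 - spec.p_female)).astype(int)
    ht = (rng.random(n) < expit(spec.ht_intercept + spec.link_slope * z_age)).astype(int)
    hyperlip = (rng.random(n) < spec.p_hyperlipemia).astype(int)
    diabetes = (rng.random(n) < spec.p_diabetes).astype(int)
    smoker = (rng.random(n) < spec.p_smoker).astype(int)

    c0, c1 = spec.dmv_cutpoints
    le0 = expit(c0 - spec.link_slope * z_age)
    le1 = expit(c1 - spec.link_slope * z_age)
    u = rng.random(n)
    dmv = np.where(u < le0, 0, np.where(u < le1, 1, 2)).astype(int)

    a_psqi = (0.0 - spec.psqi_mean) / spec.psqi_sd
    psqi = truncnorm.rvs(a_psqi, np.inf, loc=spec.psqi_mean, scale=spec.psqi_sd,
                         size=n, random_state=rng)
    icv = rng.normal(spec.icv_mean_ml, spec.icv_sd_ml, n)
    b2i = np.clip(rng.normal(spec.brain_to_icv_mean, spec.brain_to_icv_sd, n), 0.5, 0.95)
    wmh_ml = np.exp(rng.normal(np.log(spec.wmh_ml_median), spec.wmh_ml_log_sd, n))
    wmh_norm = wmh_ml / icv
    bgpvs = rng.choice(len(spec.bgpvs_probs), size=n, p=spec.bgpvs_probs)
    wmpvs = rng.choice(len(spec.wmpvs_probs), size=n, p=spec.wmpvs_probs)
    lacunes = rng.poisson(spec.lacune_rate, n)
    microbleeds = rng.poisson(spec.microbleed_rate, n)
    overlap = np.where(
        rng.random(n) < spec.wmh_overlap_zero_prob,
        0.0,
        np.round(rng.exponential(spec.wmh_overlap_mean_mm3, n) / 8.0) * 8.0,
    )

    # population-standardized planted predictors
    p_male = 1.0 - spec.p_female
    z_sex = (male - p_male) / np.sqrt(p_male * (1 - p_male))
    p_ht = spec.p_hypertension
    z_ht = (ht - p_ht) / np.sqrt(p_ht * (1 - p_ht))
    dmv_mean, dmv_var = _dmv_moments(spec.dmv_marginal)
    z_dmv = (dmv - dmv_mean) / np.sqrt(dmv_var)

    lin = (
        spec.beta_age * z_age
        + spec.beta_sex * z_sex
        + spec.beta_hypertension * z_ht
        + spec.beta_dmv * z_dmv
    )
    alps = spec.alps_mean + spec.alps_sd * lin + rng.normal(0.0, spec.resid_sd, n)
    half = rng.normal(0.0, spec.alps_lr_half_diff_sd, n)
    alps = np.maximum(alps, 0.05)  # schema requires positive ALPS; ~never binds
    alps_left = np.maximum(alps + half, 0.05)
    alps_right = np.maximum(alps - half, 0.05)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "age": age,
            "sex": male,
            "hypertension": ht,
            "hyperlipemia": hyperlip,
            "diabetes": diabetes,
            "smoker": smoker,
            "psqi": psqi,
            "icv_ml": icv,
            "brain_to_icv": b2i,
            "wmh_norm": wmh_norm,
            "bgpvs_score": bgpvs,
            "wmpvs_score": wmpvs,
            "n_lacunes": lacunes,
            "n_microbleeds": microbleeds,
            "dmv_score": dmv,
            "wmh_overlap_mm3": overlap,
            "alps_left": alps_left,
            "alps_right": alps_right,
            "alps_mean": (alps_left + alps_right) / 2.0,
        },
        columns=list(COHORT_SCHEMA_COLUMNS),
    )
    return validate_cohort(table)
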