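"""Synthetic cataract-cohort generator.

Emulates the joint structure the analysis assumes in a per-eye cohort of
elderly cataract patients, without any patient data:

* age ~ truncated normal (default 68.25 +/- 11.33 y, range 40-95);
* corneal irregularity index (IR, mm) log-linear in age with log-normal
  noise, calibrated so the marginal is ~0.042 +/- 0.019 mm;
* axis class drawn from a logistic model in age — against-the-rule
  astigmatism becomes more likely with age, so ATR eyes are older on
  average;
* automated-keratometry (AK) magnitude log-normal, flat axis near 0 deg
  (WTR, steep vertical) or 90 deg (ATR) with angular jitter;
* a TCRP-vs-AK discrepancy vector whose magnitude is log-linear in age,
  IR and AK magnitude with log-normal noise, and whose direction is
  uniform in double-angle space; TCRP3 = AK + discrepancy, TCRP4 damps
  the discrepancy by a configurable factor (default 0.9);
* TCRP3 acts as the generative "true cornea": the postoperative
  corneal-plane refractive astigmatism is the true cornea minus the true
  SIA flattening vector plus bivariate Gaussian residual noise whose
  scale grows with IR, then transported to the spectacle plane by the
  inverse vertex map;
* anterior/posterior radii drawn so the anterior-to-posterior curvature
  ratio decreases with IR.

With all noise scales at zero and the analysis SIA matching ``sia_true``
the ORA against TCRP3 is exactly zero and the ORA against AK equals the
injected discrepancy magnitude — the pipeline's noise-free identity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .powervec import CylAstig, PowerVector, normalize_axis, pv_to_cyl
from .records import EyeRecord
from .refraction import (
    SiaSpec,
    SpheroCylinder,
    inverse_vertex_correct_power,
    sia_flattening_vector,
)

__all__ = ["SimulationParams", "generate_cohort", "known_truth"]


@dataclass(frozen=True)
class SimulationParams:
    """All generative parameters; the seed fixes the cohort exactly.

    Defaults are anchored to the clinical characteristics the analysis
    targets (age 68.25 +/- 11.33 y; IR 0.042 +/- 0.019 mm; older ATR
    eyes; mean TCRP3-AK delta ~0.43 D, SD ~0.37 D; SIA 0.40 D from a
    temporal incision at a 12-mm vertex distance).
    """

    n: int = 207
    seed: int = 0

    # age (years), truncated normal
    age_mean: float = 68.25
    age_sd: float = 11.33
    age_range: tuple[float, float] = (40.0, 95.0)

    # ln(IR/mm) = intercept + slope*age + N(0, noise_sd); IR >= ir_min
    ir_log_intercept: float = -4.335
    ir_log_age_slope: float = 0.0157
    ir_log_noise_sd: float = 0.393
    ir_min: float = 0.005

    # P(ATR | age) = logistic(intercept + slope*age)
    atr_logistic_intercept: float = -4.70
    atr_logistic_age_slope: float = 0.0623
    axis_jitter_sd: float = 10.0  # degrees around the class-typical flat axis

    # AK cylinder magnitude ~ lognormal(mu, sigma), truncated to range (D)
    ak_magnitude_log_mu: float = -0.20
    ak_magnitude_log_sigma: float = 0.63
    ak_magnitude_range: tuple[float, float] = (0.1, 6.0)

    # ln(delta/D) = intercept + age_coef*age + ir_coef*IR + ak_coef*AK + N(0, noise_sd)
    delta_intercept: float = -1.867
    delta_age_coef: float = 0.007
    delta_ir_coef: float = 1.613
    delta_ak_coef: float = 0.201
    delta_noise_sd: float = 0.726
    tcrp4_damping: float = 0.9  # TCRP4 discrepancy = damping * TCRP3 discrepancy

    # refraction residual: per-component SD = ora_noise_sd * (1 + ir_scale*IR)
    ora_noise_sd: float = 0.15
    ir_scale: float = 5.0
    sia_true: SiaSpec = field(default_factory=lambda: SiaSpec(0.40, 0.0))
    vertex_distance: float = 0.012

    # corneal-plane postoperative spherical equivalent (D)
    se_mean: float = -0.25
    se_sd: float = 0.40

    # total corneal irregular astigmatism (um) = intercept + slope*IR + noise
    irregular_astig_intercept: float = 0.0
    irregular_astig_ir_slope: float = 10.0
    irregular_astig_noise_sd: float = 0.15

    # corneal spherical aberration (um), class-dependent mean
    sa_wtr_mean: float = 0.326
    sa_atr_mean: float = 0.407
    sa_sd: float = 0.20

    # radii (mm): posterior = anterior / ap_ratio, ratio decreasing in IR
    ant_radius_mean: float = 7.80
    ant_radius_sd: float = 0.25
    ap_ratio_intercept: float = 1.22
    ap_ratio_ir_slope: float = -1.0
    ap_ratio_noise_sd: float = 0.02

    def __post_init__(self):
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n!r}")
        for name in (
            "age_sd",
            "ir_log_noise_sd",
            "axis_jitter_sd",
            "ak_magnitude_log_sigma",
            "delta_noise_sd",
            "ora_noise_sd",
            "se_sd",
            "irregular_astig_noise_sd",
            "sa_sd",
            "ant_radius_sd",
            "ap_ratio_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not (0.0 <= self.tcrp4_damping):
            raise ValueError(f"tcrp4_damping must be >= 0, got {self.tcrp4_damping!r}")
        if self.vertex_distance < 0:
            raise ValueError(f"vertex_distance must be >= 0, got {self.vertex_distance!r}")


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Draw from N(mean, sd) restricted to [lo, hi] by resampling."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(params: SimulationParams | None = None) -> list[EyeRecord]:
    """Generate ``params.n`` synthetic :class:`EyeRecord` eyes.

    Deterministic given ``params.seed``; ``n=0`` yields an empty list.
    """
    params = params or SimulationParams()
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n
    if n == 0:
        return []

    age = _truncated_normal(rng, p.age_mean, p.age_sd, *p.age_range, n)

    ln_ir = p.ir_log_intercept + p.ir_log_age_slope * age + rng.normal(0.0, p.ir_log_noise_sd, n)
    ir = np.exp(ln_ir)
    low = ir < p.ir_min
    while low.any():  # resample the handful below the physical floor
        ln_ir[low] = (
            p.ir_log_intercept
            + p.ir_log_age_slope * age[low]
            + rng.normal(0.0, p.ir_log_noise_sd, int(low.sum()))
        )
        ir[low] = np.exp(ln_ir[low])
        low = ir < p.ir_min

    p_atr = 1.0 / (1.0 + np.exp(-(p.atr_logistic_intercept + p.atr_logistic_age_slope * age)))
    is_atr = rng.random(n) < p_atr

    # flat meridian near 0 deg for WTR (steep vertical), near 90 deg for ATR
    base_axis = np.where(is_atr, 90.0, 0.0)
    ak_axis = np.array(
        [normalize_axis(a) for a in base_axis + rng.normal(0.0, p.axis_jitter_sd, n)]
    )

    lo, hi = p.ak_magnitude_range
    ak_mag = np.exp(rng.normal(p.ak_magnitude_log_mu, p.ak_magnitude_log_sigma, n))
    bad = (ak_mag < lo) | (ak_mag > hi)
    while bad.any():
        ak_mag[bad] = np.exp(
            rng.normal(p.ak_magnitude_log_mu, p.ak_magnitude_log_sigma, int(bad.sum()))
        )
        bad = (ak_mag < lo) | (ak_mag > hi)

    two_a = np.radians(2.0 * ak_axis)
    ak_j0 = 0.5 * ak_mag * np.cos(two_a)
    ak_j45 = 0.5 * ak_mag * np.sin(two_a)

    # discrepancy vector between ray-traced and automated keratometry
    ln_delta = (
        p.delta_intercept
        + p.delta_age_coef * age
        + p.delta_ir_coef * ir
        + p.delta_ak_coef * ak_mag
        + rng.normal(0.0, p.delta_noise_sd, n)
    )
    delta = np.exp(ln_delta)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)  # uniform direction in (J0, J45)
    d_j0 = delta * np.cos(phi)
    d_j45 = delta * np.sin(phi)

    tcrp3_j0, tcrp3_j45 = ak_j0 + d_j0, ak_j45 + d_j45
    tcrp4_j0 = ak_j0 + p.tcrp4_damping * d_j0
    tcrp4_j45 = ak_j45 + p.tcrp4_damping * d_j45

    # postoperative corneal-plane refractive astigmatism: true cornea (TCRP3)
    # minus the true incision flattening, plus IR-scaled residual noise
    sia_pv = sia_flattening_vector(p.sia_true)
    noise_sd = p.ora_noise_sd * (1.0 + p.ir_scale * ir)
    ra_j0 = tcrp3_j0 - sia_pv.j0 + rng.normal(0.0, 1.0, n) * noise_sd
    ra_j45 = tcrp3_j45 - sia_pv.j45 + rng.normal(0.0, 1.0, n) * noise_sd

    se_corneal = rng.normal(p.se_mean, p.se_sd, n)

    irregular_astig = np.clip(
        p.irregular_astig_intercept
        + p.irregular_astig_ir_slope * ir
        + rng.normal(0.0, p.irregular_astig_noise_sd, n),
        0.0,
        None,
    )
    sa = np.clip(
        np.where(is_atr, p.sa_atr_mean, p.sa_wtr_mean) + rng.normal(0.0, p.sa_sd, n), 0.0, None
    )
    ant_radius = _truncated_normal(rng, p.ant_radius_mean, p.ant_radius_sd, 6.5, 9.5, n)
    ap_ratio = np.clip(
        p.ap_ratio_intercept + p.ap_ratio_ir_slope * ir + rng.normal(0.0, p.ap_ratio_noise_sd, n),
        1.0,
        1.5,
    )
    post_radius = ant_radius / ap_ratio

    cohort: list[EyeRecord] = []
    for i in range(n):
        ra_cyl_corneal = pv_to_cyl(PowerVector(ra_j0[i], ra_j45[i]))
        # corneal-plane positive-cylinder refraction with the drawn SE,
        # transported meridian-wise back to the spectacle plane
        s_c = se_corneal[i] - 0.5 * ra_cyl_corneal.magnitude
        f1, f2 = s_c, s_c + ra_cyl_corneal.magnitude
        g1 = inverse_vertex_correct_power(f1, p.vertex_distance)
        g2 = inverse_vertex_correct_power(f2, p.vertex_distance)
        ra_spectacle = SpheroCylinder(
            sphere=g1, cylinder=g2 - g1, axis=ra_cyl_corneal.axis, notation="positive"
        ).to_notation("negative")
        cohort.append(
            EyeRecord(
                eye_id=f"syn{i:05d}",
                age=float(age[i]),
                ak=CylAstig(float(ak_mag[i]), float(ak_axis[i])),
                tcrp3=pv_to_cyl(PowerVector(tcrp3_j0[i], tcrp3_j45[i])),
                tcrp4=pv_to_cyl(PowerVector(tcrp4_j0[i], tcrp4_j45[i])),
                ir=float(ir[i]),
                irregular_astig=float(irregular_astig[i]),
                anterior_radius=float(ant_radius[i]),
                posterior_radius=float(post_radius[i]),
                ra_postop=ra_spectacle,
                spherical_aberration=float(sa[i]),
            )
        )
    return cohort


def known_truth(params: SimulationParams | None = None) -> dict:
    """The exact generative parameter values, for recovery assertions."""
    params = params or SimulationParams()
    truth = dataclasses.asdict(params)
    truth["sia_true"] = {
        "magnitude": params.sia_true.magnitude,
        "incision_axis": params.sia_true.incision_axis,
    }
    return truth
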