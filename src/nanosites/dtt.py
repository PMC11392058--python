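"""DTT assay reduction: oxidative-potential descriptors per sample.

Dithiothreitol (DTT) is catalytically oxidized by reactive particle
surfaces; the unreacted DTT is quantified with Ellman's reagent (DTNB) at
412 nm against a linear calibration.  From the single-endpoint replicate
absorbances the module computes

* conversion    X = 100 * (C_negative - C_sample) / C0        [%]
* NIOG              X_sample / X_positive                     [-]
* OP_mass           (X/100) * C0 * V / (t * m)                [nmol h^-1 mg^-1]
* OP_area           OP_mass * 1000 / BET                      [nmol h^-1 m^-2]
* OxTOF             OP_mass / (1000 * n_sites)                [h^-1]

where C0 is the nominal initial DTT in the reactor (uM), V the reaction
volume (mL), t the incubation time (h), m the particle mass in the reactor
(mg, from the suspension concentration and volume), BET the specific
surface area (m^2 g^-1) and n_sites the specific site content
(mmol g^-1).  Conversion is net of the no-particle negative control;
NIOG references the H2O2 positive control.  OxTOF counts DTT molecules
oxidized per reactive surface site and hour, the per-site analogue of a
catalytic turnover frequency.

Negative net conversions are kept (flagged below-detection), never
clamped, so replicate means stay unbiased.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import DTTRun, SampleRecord, ValidationError

__all__ = [
    "Calibration",
    "OPResult",
    "fit_calibration",
    "absorbance_to_conc",
    "dtt_conversion",
    "niog",
    "op_mass",
    "op_area",
    "oxtof",
    "aggregate_replicates",
    "evaluate_op",
]


@dataclass(frozen=True)
class Calibration:
    """Linear A412-vs-concentration calibration of the DTT-DTNB complex."""

    slope: float  # A412 per uM
    intercept: float  # A412
    r_squared: float
    n_points: int


def fit_calibration(points) -> Calibration:
    """Ordinary least squares of absorbance on DTT concentration.

    Requires >= 3 points with non-zero concentration spread; warns when
    r^2 < 0.99 (the working range should be cleanly linear).
    """
    pts = [(float(c), float(a)) for c, a in points]
    if len(pts) < 3:
        raise ValidationError("calibration needs >= 3 points")
    conc = np.array([p[0] for p in pts])
    absb = np.array([p[1] for p in pts])
    if np.ptp(conc) <= 0:
        raise ValidationError("calibration concentrations have zero spread")
    res = stats.linregress(conc, absb)
    if res.slope <= 0:
        raise ValidationError(f"calibration slope must be > 0, got {res.slope:g}")
    r2 = float(res.rvalue**2)
    if r2 < 0.99:
        warnings.warn(f"calibration r^2 = {r2:.4f} < 0.99", stacklevel=2)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=len(pts),
    )


def absorbance_to_conc(absorbance, calibration: Calibration):
    """Invert the calibration: (A - intercept) / slope, floored at 0 uM."""
    a = np.asarray(absorbance, dtype=float)
    conc = (a - calibration.intercept) / calibration.slope
    conc = np.clip(conc, 0.0, None)
    return float(conc) if np.isscalar(absorbance) else conc


def dtt_conversion(c_sample, c_negative: float, c0_um: float):
    """Catalytic DTT conversion (%) net of the no-particle control.

    Negative values (sample indistinguishable from control) are preserved;
    callers flag them below-detection.
    """
    if c0_um <= 0:
        raise ValueError("initial DTT concentration must be > 0")
    c_sample = np.asarray(c_sample, dtype=float)
    x = 100.0 * (c_negative - c_sample) / c0_um
    return float(x) if x.ndim == 0 else x


def niog(x_sample, x_positive: float):
    """Normalized index of oxidant generation: conversion relative to the
    H2O2 positive control."""
    if x_positive <= 0:
        raise ValueError("positive-control conversion must be > 0")
    x = np.asarray(x_sample, dtype=float) / x_positive
    return float(x) if x.ndim == 0 else x


def op_mass(x_percent, c0_um: float, volume_ml: float, time_h: float, mass_mg: float):
    """Mass-specific DTT depletion rate (nmol h^-1 mg^-1).

    uM * mL = nmol, so the converted amount is (X/100) * C0 * V nmol.
    """
    if time_h <= 0:
        raise ValueError("time_h must be > 0")
    if mass_mg <= 0:
        raise ValueError("mass_mg must be > 0")
    x = np.asarray(x_percent, dtype=float)
    rate = (x / 100.0) * c0_um * volume_ml / (time_h * mass_mg)
    return float(rate) if rate.ndim == 0 else rate


def op_area(op_mass_value, bet_m2_per_g: float):
    """Surface-specific rate (nmol h^-1 m^-2): OP_mass * 1000 (mg/g) / BET."""
    if bet_m2_per_g <= 0:
        raise ValueError("bet_m2_per_g must be > 0")
    r = np.asarray(op_mass_value, dtype=float) * 1e3 / bet_m2_per_g
    return float(r) if r.ndim == 0 else r


def oxtof(op_mass_value, specific_sites_mmol_g: float):
    """Oxidative turnover frequency (h^-1): DTT molecules oxidized per
    reactive site per hour.  1 mmol g^-1 of sites = 1000 nmol mg^-1."""
    if specific_sites_mmol_g <= 0:
        raise ValueError("specific_sites_mmol_g must be > 0")
    r = np.asarray(op_mass_value, dtype=float) / (1e3 * specific_sites_mmol_g)
    return float(r) if r.ndim == 0 else r


def aggregate_replicates(values) -> tuple[float, float, bool]:
    """Mean and sample standard deviation (n-1); singleton sd is 0, flagged."""
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("no replicate values")
    if arr.size == 1:
        return float(arr[0]), 0.0, True
    return float(np.mean(arr)), float(np.std(arr, ddof=1)), False


@dataclass
class OPResult:
    """All oxidative-potential descriptors for one sample, with replicate
    dispersion and the per-replicate values needed downstream."""

    sample_id: str
    conversion_pct: float
    conversion_sd: float
    niog: float
    niog_sd: float
    op_mass: float
    op_mass_sd: float
    op_area: float | None
    op_area_sd: float | None
    oxtof: float | None
    oxtof_sd: float | None
    mass_in_reactor_mg: float
    below_detection: bool
    dissolution_suspect: bool
    singleton: bool = False
    replicates: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def evaluate_op(
    run: DTTRun,
    sample: SampleRecord | None = None,
    specific_sites_mmol_g: float | None = None,
    calibration: Calibration | None = None,
) -> OPResult:
    """Reduce one DTT run to descriptors.

    The particle mass in the reactor is computed from the mixing protocol
    (suspension concentration times reaction volume).  OP_area needs a
    sample record (BET); OxTOF needs a positive specific site content —
    both stay ``None`` otherwise.
    """
    cal = calibration if calibration is not None else fit_calibration(run.calibration_points)
    c_sample = absorbance_to_conc(run.absorbance_sample, cal)
    c_negative = float(np.mean(absorbance_to_conc(run.absorbance_negative, cal)))
    c_positive = absorbance_to_conc(run.absorbance_positive, cal)
    c0 = run.initial_dtt_um

    x_i = np.atleast_1d(dtt_conversion(c_sample, c_negative, c0))
    x_pos_i = np.atleast_1d(dtt_conversion(c_positive, c_negative, c0))
    x_pos = float(np.mean(x_pos_i))
    niog_i = np.atleast_1d(niog(x_i, x_pos))

    mass_mg = run.enm_concentration_ug_ml * run.reaction_volume_ml / 1000.0
    op_mass_i = np.atleast_1d(
        op_mass(x_i, c0, run.reaction_volume_ml, run.incubation_time_h, mass_mg)
    )

    x_mean, x_sd, singleton = aggregate_replicates(x_i)
    n_mean, n_sd, _ = aggregate_replicates(niog_i)
    m_mean, m_sd, _ = aggregate_replicates(op_mass_i)

    replicates: dict[str, np.ndarray] = {
        "conversion_pct": x_i,
        "niog": niog_i,
        "op_mass": op_mass_i,
    }

    a_mean = a_sd = None
    if sample is not None:
        op_area_i = np.atleast_1d(op_area(op_mass_i, sample.bet_m2_per_g))
        a_mean, a_sd, _ = aggregate_replicates(op_area_i)
        replicates["op_area"] = op_area_i

    t_mean = t_sd = None
    if specific_sites_mmol_g is not None and specific_sites_mmol_g > 0:
        oxtof_i = np.atleast_1d(oxtof(op_mass_i, specific_sites_mmol_g))
        t_mean, t_sd, _ = aggregate_replicates(oxtof_i)
        replicates["oxtof"] = oxtof_i

    return OPResult(
        sample_id=run.sample_id,
        conversion_pct=x_mean,
        conversion_sd=x_sd,
        niog=n_mean,
        niog_sd=n_sd,
        op_mass=m_mean,
        op_mass_sd=m_sd,
        op_area=a_mean,
        op_area_sd=a_sd,
        oxtof=t_mean,
        oxtof_sd=t_sd,
        mass_in_reactor_mg=mass_mg,
        below_detection=bool(x_mean <= 0),
        dissolution_suspect=run.dissolution_suspect,
        singleton=singleton,
        replicates=replicates,
    )
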