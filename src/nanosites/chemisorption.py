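"""Reactive-site titration from methanol breakthrough curves.

During chemisorption the sample is fed a constant methanol stream (2000 ppm
in argon, 5% helium internal standard) until the outlet concentration
saturates at the feed level.  Methanol titrates surface hydroxyls 1:1 —
each chemisorbed molecule converts to a surface methoxy and releases one
water — so the moles held back by the bed count the reactive surface sites.

The uptake is the area between feed and outlet curves,

    n_ads = F_MeOH * integral( 1 - y_out(t) / y_feed ) dt ,

with F_MeOH the methanol molar feed rate and y_out the outlet mole
fraction, obtained from the raw ion currents by internal-standard
normalization (target/He ratio, rescaled so the saturation plateau equals
the feed fraction).  Dividing the helium channel out cancels any source or
detector drift common to both channels.  Specific site content (mmol per
gram) and site surface density (sites per nm^2 of BET area) follow by
normalization.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core_io import MSTimeSeries, SampleRecord, ValidationError

__all__ = [
    "GAS_CONSTANT_L_ATM",
    "AVOGADRO",
    "SiteQuantification",
    "NormalizedBreakthrough",
    "UnsaturatedRunError",
    "feed_molar_flow",
    "normalize_to_internal_standard",
    "integrate_uptake",
    "blank_correct",
    "quantify_sites",
    "site_density",
    "quantify_from_trace",
]

GAS_CONSTANT_L_ATM = 0.0820573661  # L atm K^-1 mol^-1
AVOGADRO = 6.02214076e23  # mol^-1


class UnsaturatedRunError(ValidationError):
    """The breakthrough curve never reached its saturation plateau."""


class NormalizedBreakthrough(NamedTuple):
    """Drift-corrected outlet methanol fraction against time."""

    time_s: np.ndarray
    y_ppm: np.ndarray
    y_feed_ppm: float


@dataclass(frozen=True)
class SiteQuantification:
    """Chemisorption result for one sample."""

    uptake_umol: float
    blank_uptake_umol: float
    specific_sites_mmol_g: float | None
    site_density_per_nm2: float | None
    feed_molar_flow_umol_min: float
    below_detection: bool = False


def feed_molar_flow(
    flow_ml_min: float,
    fraction_ppm: float,
    t_ref_c: float = 25.0,
    p_atm: float = 1.0,
) -> float:
    """Methanol molar feed rate (umol min^-1) from the volumetric flow.

    Ideal gas at the stated reference conditions; 100 mL min^-1 of 2000 ppm
    methanol at 25 degC / 1 atm is ~8.18 umol min^-1.
    """
    if flow_ml_min <= 0:
        raise ValueError("flow must be > 0")
    if not 0 <= fraction_ppm <= 1e6:
        raise ValueError("fraction_ppm must be within [0, 1e6]")
    if t_ref_c <= -273.15:
        raise ValueError("reference temperature below absolute zero")
    if p_atm <= 0:
        raise ValueError("pressure must be > 0")
    total_mol_min = p_atm * (flow_ml_min / 1000.0) / (
        GAS_CONSTANT_L_ATM * (t_ref_c + 273.15)
    )
    return total_mol_min * 1e6 * fraction_ppm * 1e-6


def normalize_to_internal_standard(
    trace: MSTimeSeries,
    target_mz: int = 31,
    standard_mz: int | None = None,
    plateau_fraction: float = 0.1,
) -> NormalizedBreakthrough:
    """Outlet mole fraction from the target/internal-standard current ratio.

    The ratio r(t) = I_target / I_standard removes drift common to both
    channels; it is then rescaled so the mean over the final
    ``plateau_fraction`` of the run equals the feed fraction, anchoring the
    saturated plateau at y_feed.
    """
    if standard_mz is None:
        standard_mz = trace.meta.internal_standard_mz
    target = trace.channel(target_mz)
    standard = trace.channel(standard_mz)
    if np.any(standard <= 0):
        raise ValidationError(
            f"run {trace.run_id!r}: internal-standard channel mz_{standard_mz} "
            "contains non-positive values; ratio undefined"
        )
    ratio = target / standard
    n_tail = max(int(round(plateau_fraction * ratio.size)), 3)
    tail_mean = float(np.mean(ratio[-n_tail:]))
    if tail_mean <= 0:
        raise ValidationError(
            f"run {trace.run_id!r}: saturation plateau signal is not positive"
        )
    y_feed = trace.meta.feed_fraction_ppm
    scale = y_feed / tail_mean
    return NormalizedBreakthrough(trace.time_s, ratio * scale, y_feed)


def _plateau_slope_ok(
    time_min: np.ndarray,
    y: np.ndarray,
    tail_fraction: float,
    slope_tol_per_min: float,
) -> tuple[bool, float]:
    """Saturation test on the final window.

    Least-squares slope of the last ``tail_fraction`` of the window,
    relative to the plateau level.  The run counts as unsaturated when the
    slope exceeds the tolerance by more than twice its own standard error,
    so plateau noise alone cannot trip the test while a still-rising front
    (slope far above tolerance) always does.
    """
    n_tail = max(int(round(tail_fraction * y.size)), 3)
    t = time_min[-n_tail:]
    v = y[-n_tail:]
    plateau = float(np.mean(v))
    slope, intercept = np.polyfit(t, v, 1)
    resid = v - (slope * t + intercept)
    dof = max(n_tail - 2, 1)
    sxx = float(np.sum((t - np.mean(t)) ** 2))
    se = float(np.sqrt(np.sum(resid**2) / dof / max(sxx, 1e-30)))
    denom = max(abs(plateau), 1e-30)
    rel_slope = abs(float(slope)) / denom
    rel_se = se / denom
    return rel_slope - 2.0 * rel_se <= slope_tol_per_min, rel_slope


def integrate_uptake(
    normalized: NormalizedBreakthrough,
    feed_flow_umol_min: float,
    window_s: tuple[float, float] | None = None,
    tail_fraction: float = 0.1,
    plateau_slope_tol: float = 0.005,
) -> float:
    """Chemisorbed amount (umol) from the area between feed and outlet.

    Trapezoidal rule on the native time grid (no resampling).  The run must
    be saturated: the least-squares slope of the final ``tail_fraction`` of
    the window has to stay below ``plateau_slope_tol`` (fraction of the
    plateau value per minute), otherwise :class:`UnsaturatedRunError`.
    """
    t = normalized.time_s
    y = normalized.y_ppm
    if window_s is not None:
        lo, hi = window_s
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
            raise ValueError("integration window outside the recorded series")
        mask = (t >= lo) & (t <= hi)
        t, y = t[mask], y[mask]
    if t.size < 4:
        raise ValidationError("integration window holds too few points")
    t_min = t / 60.0
    ok, rel = _plateau_slope_ok(t_min, y, tail_fraction, plateau_slope_tol)
    if not ok:
        raise UnsaturatedRunError(
            "unsaturated run: final-window slope "
            f"{rel:.3g} of plateau per minute exceeds {plateau_slope_tol:g}"
        )
    integrand = 1.0 - y / normalized.y_feed_ppm
    return float(feed_flow_umol_min * np.trapezoid(integrand, t_min))


def blank_correct(uptake_umol: float, blank_uptake_umol: float) -> tuple[float, bool]:
    """Subtract the inert-bed (SiC) blank uptake.

    A negative difference is clamped to 0 and flagged below-detection so
    inert samples flow through the pipeline instead of erroring.
    """
    if uptake_umol < 0 or blank_uptake_umol < 0:
        raise ValueError("uptakes must be >= 0")
    net = uptake_umol - blank_uptake_umol
    if net < 0:
        return 0.0, True
    return net, False


def quantify_sites(uptake_umol: float, mass_mg: float) -> float:
    """Specific site content (mmol g^-1), one site per chemisorbed methanol."""
    if mass_mg <= 0:
        raise ValueError("mass_mg must be > 0")
    return uptake_umol / mass_mg  # umol/mg == mmol/g


def site_density(specific_sites_mmol_g: float, bet_m2_per_g: float) -> float:
    """Reactive sites per nm^2 of BET surface."""
    if bet_m2_per_g <= 0:
        raise ValueError("bet_m2_per_g must be > 0")
    sites_per_g = specific_sites_mmol_g * 1e-3 * AVOGADRO
    return sites_per_g / (bet_m2_per_g * 1e18)


def quantify_from_trace(
    trace: MSTimeSeries,
    sample: SampleRecord | None = None,
    blank_trace: MSTimeSeries | None = None,
    blank_uptake_umol: float = 0.0,
    target_mz: int = 31,
    window_s: tuple[float, float] | None = None,
    **integrate_opts,
) -> SiteQuantification:
    """Full breakthrough analysis: normalize, integrate, blank-correct and
    (when a sample record is supplied) convert to specific sites and site
    surface density."""
    meta = trace.meta
    flow = feed_molar_flow(
        meta.total_flow_ml_min, meta.feed_fraction_ppm, meta.reference_temp_c, meta.pressure_atm
    )
    norm = normalize_to_internal_standard(trace, target_mz=target_mz)
    uptake = integrate_uptake(norm, flow, window_s=window_s, **integrate_opts)
    if blank_trace is not None:
        bmeta = blank_trace.meta
        bflow = feed_molar_flow(
            bmeta.total_flow_ml_min,
            bmeta.feed_fraction_ppm,
            bmeta.reference_temp_c,
            bmeta.pressure_atm,
        )
        bnorm = normalize_to_internal_standard(blank_trace, target_mz=target_mz)
        blank_uptake_umol = max(integrate_uptake(bnorm, bflow, **integrate_opts), 0.0)
    net, flagged = blank_correct(max(uptake, 0.0), blank_uptake_umol)
    sites = density = None
    if sample is not None:
        sites = quantify_sites(net, sample.mass_mg)
        density = site_density(sites, sample.bet_m2_per_g)
    return SiteQuantification(
        uptake_umol=net,
        blank_uptake_umol=blank_uptake_umol,
        specific_sites_mmol_g=sites,
        site_density_per_nm2=density,
        feed_molar_flow_umol_min=flow,
        below_detection=flagged,
    )
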