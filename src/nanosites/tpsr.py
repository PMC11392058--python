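"""Temperature-programmed surface reaction (TPSR) analysis.

After methanol saturation the surface is heated under inert flow and the
chemisorbed methoxy groups react; the product slate diagnoses the site
nature.  Dimethyl ether (m/z 45) forms on acid sites, formaldehyde (m/z 30)
on redox sites, and CO2 (m/z 44) either on basic sites (release at high
temperature, carbonate decomposition) or on strongly oxidizing sites that
fully combust the methoxy (release at low temperature, formate
decomposition).  Lower peak temperatures signal more reactive sites.

The module extracts per-product traces from the ramp segment, removes a
linear baseline, locates peaks (Savitzky-Golay smoothed local maxima),
integrates product areas and classifies the material (acidic / basic /
redox / oxidizing-redox / mixed), including coordinates for a 2-D
reactivity map whose x axis scores oxidizing character and whose y axis
runs from acidic (-1) to basic (+1).  Channels are treated as product-pure;
fragmentation overlap between m/z values is not deconvolved.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .core_io import MSTimeSeries, ValidationError

__all__ = [
    "DEFAULT_MZ_PRODUCTS",
    "PRODUCT_MZ",
    "STRENGTH_REFERENCE_C",
    "TPSRPeak",
    "SiteNatureProfile",
    "extract_product_traces",
    "baseline_correct",
    "detect_peaks",
    "integrate_products",
    "classify_nature",
    "reactivity_map_coordinates",
    "analyze_tpsr",
]

logger = logging.getLogger(__name__)

#: m/z assignment of the monitored products.
DEFAULT_MZ_PRODUCTS: dict[int, str] = {
    31: "CH3OH",
    30: "HCHO",
    45: "DME",
    60: "methylformate",
    75: "dimethoxymethane",
    18: "H2O",
    44: "CO2",
}
PRODUCT_MZ = {v: k for k, v in DEFAULT_MZ_PRODUCTS.items()}

#: Products entering the acid/redox/basic classification.
CLASSIFIED_PRODUCTS = ("DME", "HCHO", "CO2")

#: Peak-temperature references separating strong (more reactive, lower T)
#: from moderate site strength, per diagnostic product.
STRENGTH_REFERENCE_C: dict[str, float] = {"DME": 345.0, "HCHO": 300.0, "CO2": 275.0}


@dataclass(frozen=True)
class TPSRPeak:
    product: str
    t_max_c: float
    height: float
    area: float
    fwhm_c: float


@dataclass
class SiteNatureProfile:
    """Acid/basic/redox character of one material's TPSR run."""

    areas: dict[str, float]
    peaks: list[TPSRPeak]
    fraction_acid: float
    fraction_redox: float
    fraction_basic: float
    label: str
    strength: str
    map_x: float = 0.0
    map_y: float = 0.0
    unreactive: bool = False
    co2_basic_threshold_c: float = 300.0
    _contributions: dict[str, float] = field(default_factory=dict, repr=False)


def _find_ramp(trace: MSTimeSeries, min_span_c: float = 50.0) -> slice:
    """Longest contiguous non-decreasing temperature segment; must climb by
    at least ``min_span_c``."""
    temp = trace.temperature_c
    rising = np.diff(temp) >= -1e-9
    best = (0, 0)
    start = 0
    for i, r in enumerate(rising):
        if not r:
            start = i + 1
        elif (i + 1 - start) > (best[1] - best[0]):
            best = (start, i + 1)
    lo, hi = best
    if hi <= lo or temp[hi] - temp[lo] < min_span_c:
        raise ValidationError(
            f"run {trace.run_id!r}: no monotone ramp segment "
            f"spanning >= {min_span_c:g} degC found"
        )
    return slice(lo, hi + 1)


def extract_product_traces(
    trace: MSTimeSeries,
    mz_map: dict[int, str] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-product (temperature, signal) series over the ramp segment,
    internal-standard normalized.  Channels with an unmapped m/z are
    skipped with a logged warning."""
    if mz_map is None:
        mz_map = DEFAULT_MZ_PRODUCTS
    seg = _find_ramp(trace)
    std_mz = trace.meta.internal_standard_mz
    standard = trace.channel(std_mz)[seg]
    if np.any(standard <= 0):
        raise ValidationError(
            f"run {trace.run_id!r}: internal-standard channel contains non-positive values"
        )
    temp = trace.temperature_c[seg]
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for mz, signal in trace.channels.items():
        if mz == std_mz:
            continue
        if mz not in mz_map:
            logger.warning("run %r: ignoring unmapped channel mz_%d", trace.run_id, mz)
            continue
        out[mz_map[mz]] = (temp, signal[seg] / standard)
    return out


def baseline_correct(
    temperature_c: np.ndarray,
    signal: np.ndarray,
    edge_fraction: float = 0.1,
) -> np.ndarray:
    """Subtract a linear baseline anchored at both temperature extremes.

    Each anchor is the mean of the lowest-decile signal within the first /
    last ``edge_fraction`` of points, placed at that window's mean
    temperature; the corrected signal is floored at 0.
    """
    temperature_c = np.asarray(temperature_c, dtype=float)
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 10:
        raise ValidationError("baseline correction needs >= 10 points")
    k = max(int(round(edge_fraction * n)), 3)

    def anchor(idx: np.ndarray) -> tuple[float, float]:
        vals = signal[idx]
        cut = np.quantile(vals, 0.1)
        sel = idx[vals <= cut]
        if sel.size == 0:
            sel = idx
        # anchor at the mean temperature of the selected points, so a
        # sloped baseline is followed exactly instead of being averaged
        # across the whole edge window
        return float(np.mean(temperature_c[sel])), float(np.mean(signal[sel]))

    t1, v1 = anchor(np.arange(k))
    t2, v2 = anchor(np.arange(n - k, n))
    if t2 == t1:
        baseline = np.full(n, 0.5 * (v1 + v2))
    else:
        baseline = v1 + (v2 - v1) * (temperature_c - t1) / (t2 - t1)
    return np.clip(signal - baseline, 0.0, None)


def detect_peaks(
    temperature_c: np.ndarray,
    signal: np.ndarray,
    product: str = "",
    min_prominence: float = 0.05,
    smooth_window: int = 11,
    smooth_order: int = 2,
    prominence_ref: float | None = None,
) -> list[TPSRPeak]:
    """Local maxima of the smoothed, baseline-corrected signal.

    Prominence threshold is ``min_prominence`` times ``prominence_ref``
    (default: the maximum of this smoothed trace; a run-wide maximum across
    products should be passed when analysing several channels so minor
    channels do not resolve their noise floor); t_max is the temperature of
    the smoothed maximum and the FWHM comes from half-height crossings.  An
    empty list is legal.
    """
    temperature_c = np.asarray(temperature_c, dtype=float)
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if n < 5 or np.max(signal) <= 0:
        return []
    win = min(smooth_window, n if n % 2 == 1 else n - 1)
    if win <= smooth_order:
        smoothed = signal
    else:
        smoothed = savgol_filter(signal, win, smooth_order)
    top = float(np.max(smoothed))
    if top <= 0:
        return []
    ref = top if prominence_ref is None else float(prominence_ref)
    idx, props = find_peaks(smoothed, prominence=min_prominence * ref)
    if idx.size == 0:
        return []
    widths, _, left_ips, right_ips = peak_widths(smoothed, idx, rel_height=0.5)
    positions = np.arange(n, dtype=float)
    t_left = np.interp(left_ips, positions, temperature_c)
    t_right = np.interp(right_ips, positions, temperature_c)
    peaks: list[TPSRPeak] = []
    for j, i in enumerate(idx):
        lb = int(props["left_bases"][j])
        rb = int(props["right_bases"][j])
        area = float(np.trapezoid(signal[lb : rb + 1], temperature_c[lb : rb + 1]))
        # refine t_max: intensity-weighted centroid over the half-height
        # region (unbiased for symmetric peaks, far less grid jitter than
        # the discrete argmax)
        lo = int(np.ceil(left_ips[j]))
        hi = int(np.floor(right_ips[j]))
        t_max = float(temperature_c[i])
        if hi > lo:
            w = smoothed[lo : hi + 1]
            if np.sum(w) > 0:
                t_max = float(np.average(temperature_c[lo : hi + 1], weights=w))
        peaks.append(
            TPSRPeak(
                product=product,
                t_max_c=t_max,
                height=float(smoothed[i]),
                area=max(area, 0.0),
                fwhm_c=float(max(t_right[j] - t_left[j], 1e-12)),
            )
        )
    return peaks


def integrate_products(
    traces: dict[str, tuple[np.ndarray, np.ndarray]],
) -> dict[str, float]:
    """Trapezoidal area over temperature of each (corrected) product trace."""
    return {
        product: float(np.trapezoid(signal, temp))
        for product, (temp, signal) in traces.items()
    }


def _dominant_peak(peaks: list[TPSRPeak], product: str) -> TPSRPeak | None:
    cand = [p for p in peaks if p.product == product]
    if not cand:
        return None
    return max(cand, key=lambda p: p.area)


def classify_nature(
    areas: dict[str, float],
    peaks: list[TPSRPeak],
    co2_basic_threshold_c: float = 300.0,
    mixed_threshold: float = 0.5,
) -> SiteNatureProfile:
    """Acid/basic/redox shares and a categorical label.

    The DME area counts toward acid sites, the HCHO area toward redox
    sites; the CO2 area counts as redox when its dominant peak sits at or
    below ``co2_basic_threshold_c`` (total oxidation on strongly oxidizing
    sites) and as basic above it (carbonate decomposition).  The label is
    the argmax share — "oxidizing-redox" when the redox share is carried by
    low-temperature CO2, "mixed" when no share reaches ``mixed_threshold``.
    Strength is "strong" when the dominant product's peak lies below its
    reference temperature, else "moderate".  CO2 area with no detected peak
    carries no temperature information and is left out of the shares.
    """
    acid = max(areas.get("DME", 0.0), 0.0)
    hcho = max(areas.get("HCHO", 0.0), 0.0)
    co2 = max(areas.get("CO2", 0.0), 0.0)
    co2_peak = _dominant_peak(peaks, "CO2")
    co2_redox = co2_basic = 0.0
    if co2 > 0 and co2_peak is not None:
        if co2_peak.t_max_c <= co2_basic_threshold_c:
            co2_redox = co2
        else:
            co2_basic = co2
    redox = hcho + co2_redox
    basic = co2_basic
    total = acid + redox + basic

    if total <= 0:
        return SiteNatureProfile(
            areas=dict(areas),
            peaks=list(peaks),
            fraction_acid=float("nan"),
            fraction_redox=float("nan"),
            fraction_basic=float("nan"),
            label="unreactive",
            strength="moderate",
            unreactive=True,
            co2_basic_threshold_c=co2_basic_threshold_c,
        )

    f_acid, f_redox, f_basic = acid / total, redox / total, basic / total
    shares = {"acidic": f_acid, "redox": f_redox, "basic": f_basic}
    label = max(shares, key=shares.get)
    if shares[label] < mixed_threshold:
        label = "mixed"
    elif label == "redox" and co2_redox > hcho:
        label = "oxidizing-redox"

    contributions = {"DME": acid, "HCHO": hcho, "CO2": co2_redox + co2_basic}
    dominant = max(contributions, key=contributions.get)
    dom_peak = _dominant_peak(peaks, dominant)
    strength = "moderate"
    if dom_peak is not None and dom_peak.t_max_c < STRENGTH_REFERENCE_C[dominant]:
        strength = "strong"

    profile = SiteNatureProfile(
        areas=dict(areas),
        peaks=list(peaks),
        fraction_acid=f_acid,
        fraction_redox=f_redox,
        fraction_basic=f_basic,
        label=label,
        strength=strength,
        co2_basic_threshold_c=co2_basic_threshold_c,
        _contributions={"acid": acid, "hcho": hcho, "co2_redox": co2_redox, "basic": basic},
    )
    profile.map_x, profile.map_y = reactivity_map_coordinates(profile)
    return profile


def reactivity_map_coordinates(
    profile: SiteNatureProfile,
    t_low_c: float = 150.0,
    t_high_c: float = 450.0,
) -> tuple[float, float]:
    """Heuristic 2-D reactivity-map coordinates.

    y = (basic - acid) / (acid + basic + redox) runs from -1 (purely
    acidic) to +1 (purely basic).  x is the redox share scaled by
    1 - (T_redox - t_low)/(t_high - t_low), where T_redox is the
    area-weighted mean peak temperature of the redox-contributing products,
    so lower reaction temperatures (more oxidizing surfaces) score larger x.
    An unreactive profile maps to (0, 0).
    """
    if profile.unreactive:
        return 0.0, 0.0
    y = profile.fraction_basic - profile.fraction_acid

    redox_peaks: list[TPSRPeak] = []
    for p in profile.peaks:
        if p.product == "HCHO":
            redox_peaks.append(p)
        elif p.product == "CO2" and p.t_max_c <= profile.co2_basic_threshold_c:
            redox_peaks.append(p)
    if profile.fraction_redox <= 0 or not redox_peaks:
        return 0.0, float(y)
    w = np.array([p.area for p in redox_peaks])
    t = np.array([p.t_max_c for p in redox_peaks])
    if w.sum() <= 0:
        w = np.ones_like(w)
    t_redox = float(np.average(t, weights=w))
    temp_score = 1.0 - (t_redox - t_low_c) / (t_high_c - t_low_c)
    x = profile.fraction_redox * float(np.clip(temp_score, 0.0, 1.0))
    return float(x), float(y)


def analyze_tpsr(
    trace: MSTimeSeries,
    mz_map: dict[int, str] | None = None,
    co2_basic_threshold_c: float = 300.0,
    min_prominence: float = 0.05,
    smooth_window: int = 11,
    smooth_order: int = 2,
) -> SiteNatureProfile:
    """Full chain: extract, baseline-correct, detect, integrate, classify."""
    raw = extract_product_traces(trace, mz_map)
    corrected: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for product, (temp, signal) in raw.items():
        corrected[product] = (temp, baseline_correct(temp, signal))
    global_max = max((float(np.max(sig)) for _, sig in corrected.values()), default=0.0)
    peaks: list[TPSRPeak] = []
    for product, (temp, corr) in corrected.items():
        peaks.extend(
            detect_peaks(
                temp,
                corr,
                product=product,
                min_prominence=min_prominence,
                smooth_window=smooth_window,
                smooth_order=smooth_order,
                prominence_ref=global_max if global_max > 0 else None,
            )
        )
    areas = integrate_products(corrected)
    return classify_nature(
        {k: v for k, v in areas.items() if k in CLASSIFIED_PRODUCTS},
        peaks,
        co2_basic_threshold_c=co2_basic_threshold_c,
    )
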