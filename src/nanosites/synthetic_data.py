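"""Seeded synthetic instrument and assay data with ground-truth records.

The generators emulate the statistical structure of the measurements the
analysis assumes — they are emulations of what the instruments record, not
physical simulations of the reactor or the assay chemistry:

* chemisorption breakthrough: a logistic front
  y(t) = y_feed / (1 + exp(-(t - t_b)/tau)) in the outlet methanol
  fraction, a shared multiplicative source drift applied to both the
  methanol and the helium internal-standard channels, and multiplicative
  Gaussian noise per channel (default 1% relative);
* TPSR: a linear temperature ramp (10 degC min^-1, 50-450 degC) with one
  Gaussian peak per product at stated temperatures on a small linear
  baseline;
* DTT: first-order depletion C(t) = C0 exp(-(k + k0) t) against a
  background rate k0, read out through a known linear calibration with
  additive absorbance noise (default 0.002 A); per-replicate catalytic
  rates carry mean-corrected lognormal variation (default 20% relative).

Every generated artifact is accompanied by a :class:`TruthRecord`; no
analysis stage reads the truth.  All randomness flows through one
``numpy.random.default_rng(seed)`` per call, so equal seeds give
bit-identical outputs.

``DEFAULT_PANEL`` encodes the eight-material study: printed BET areas,
specific site contents (printed, or implied by printed gravimetric/site
dose pairs), product peak temperatures, and per-site oxidation-rate tiers
in the stated ratios (the top tier fourfold above ceria; the bottom tier
roughly threefold below it).
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DTTRun,
    MSTimeSeries,
    Phase,
    RunMeta,
    SampleRecord,
    write_dtt_table,
    write_ms_timeseries,
    write_sample_sheet,
)
from .tpsr import PRODUCT_MZ

__all__ = [
    "TruthRecord",
    "PanelBundle",
    "DEFAULT_PANEL",
    "gen_breakthrough",
    "gen_blank",
    "gen_tpsr_profile",
    "gen_dtt_run",
    "gen_panel",
    "write_panel",
    "k_for_conversion",
    "conversion_for_rate",
]


@dataclass
class TruthRecord:
    """Ground truth attached to a generated artifact."""

    run_id: str
    seed: int
    true_uptake_umol: float | None = None
    breakthrough_midpoint_min: float | None = None
    front_width_min: float | None = None
    drift_amplitude: float = 0.0
    noise_sd: float = 0.0
    tpsr_peaks: list[tuple[str, float, float, float]] = field(default_factory=list)
    dtt_rate_constant_h: float | None = None
    dtt_background_rate_h: float | None = None
    true_conversion_pct: float | None = None
    true_positive_conversion_pct: float | None = None
    specific_sites_mmol_g: float | None = None
    oxtof_mean_h: float | None = None


# ---------------------------------------------------------------------------
# chemisorption breakthrough


def _drift(t: np.ndarray, amplitude: float) -> np.ndarray:
    """Linear multiplicative source drift over the run."""
    if t[-1] <= t[0]:
        return np.ones_like(t)
    return 1.0 + amplitude * (t - t[0]) / (t[-1] - t[0])


def gen_breakthrough(
    run_id: str = "sim-breakthrough",
    t_b_min: float = 10.0,
    front_width_min: float = 0.5,
    noise_sd: float = 0.01,
    drift_amplitude: float = 0.05,
    seed: int = 0,
    meta: RunMeta | None = None,
    dt_s: float = 1.0,
    t_end_min: float | None = None,
    temperature_c: float = 100.0,
) -> tuple[MSTimeSeries, TruthRecord]:
    """Synthetic chemisorption-phase MS series with a logistic front.

    The true uptake is computed on a 10x denser noise-free grid by the same
    area-between-curves definition the method rests on, independently of
    the analysis code path.
    """
    if front_width_min <= 0:
        raise ValueError("front_width_min must be > 0")
    if t_b_min < 0:
        raise ValueError("t_b_min must be >= 0")
    if meta is None:
        meta = RunMeta()
    rng = np.random.default_rng(seed)
    if t_end_min is None:
        t_end_min = t_b_min + max(10.0 * front_width_min, 8.0)
    t_s = np.arange(0.0, t_end_min * 60.0 + 0.5 * dt_s, dt_s)
    t_min = t_s / 60.0
    y_feed = meta.feed_fraction_ppm

    def outlet(tm: np.ndarray) -> np.ndarray:
        z = np.clip((tm - t_b_min) / front_width_min, -500, 500)
        return y_feed / (1.0 + np.exp(-z))

    y = outlet(t_min)
    g = _drift(t_min, drift_amplitude)
    he_level = 2.0e-9  # arbitrary ion-current units
    meoh_per_ppm = 1.5e-12
    i_he = he_level * g * (1.0 + noise_sd * rng.standard_normal(t_s.size))
    i_meoh = meoh_per_ppm * y * g * (1.0 + noise_sd * rng.standard_normal(t_s.size))
    i_he = np.clip(i_he, he_level * 1e-3, None)
    i_meoh = np.clip(i_meoh, 0.0, None)

    series = MSTimeSeries(
        run_id=run_id,
        phase=Phase.CHEMISORPTION,
        time_s=t_s,
        temperature_c=np.full(t_s.size, float(temperature_c)),
        channels={31: i_meoh, meta.internal_standard_mz: i_he},
        meta=meta,
    )

    from .chemisorption import feed_molar_flow  # local import to avoid cycle

    flow = feed_molar_flow(
        meta.total_flow_ml_min, meta.feed_fraction_ppm, meta.reference_temp_c, meta.pressure_atm
    )
    dense = np.linspace(0.0, t_end_min, 10 * t_s.size)
    true_uptake = float(flow * np.trapezoid(1.0 - outlet(dense) / y_feed, dense))
    truth = TruthRecord(
        run_id=run_id,
        seed=seed,
        true_uptake_umol=true_uptake,
        breakthrough_midpoint_min=t_b_min,
        front_width_min=front_width_min,
        drift_amplitude=drift_amplitude,
        noise_sd=noise_sd,
    )
    return series, truth


def gen_blank(
    seed: int = 0,
    run_id: str = "sim-blank",
    dead_time_min: float = 0.3,
    front_width_min: float = 0.1,
    noise_sd: float = 0.01,
    drift_amplitude: float = 0.05,
    meta: RunMeta | None = None,
    t_end_min: float = 10.0,
    **kwargs,
) -> tuple[MSTimeSeries, TruthRecord]:
    """Inert-bed (SiC) blank: near-instant breakthrough, tiny uptake."""
    return gen_breakthrough(
        run_id=run_id,
        t_b_min=dead_time_min,
        front_width_min=front_width_min,
        noise_sd=noise_sd,
        drift_amplitude=drift_amplitude,
        seed=seed,
        meta=meta,
        t_end_min=t_end_min,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# TPSR


def gen_tpsr_profile(
    peaks: Sequence[tuple[str, float, float, float]],
    seed: int = 0,
    run_id: str = "sim-tpsr",
    ramp_rate_c_min: float = 10.0,
    t_start_c: float = 50.0,
    t_end_c: float = 450.0,
    dt_s: float = 2.0,
    noise_sd: float = 0.01,
    baseline_level: float = 0.02,
    baseline_slope_per_c: float = 2.5e-5,
    meta: RunMeta | None = None,
) -> tuple[MSTimeSeries, TruthRecord]:
    """Synthetic TPSR-phase MS series.

    ``peaks`` is a list of (product, center degC, height, sigma degC); each
    product's channel carries the sum of its Gaussians on a small linear
    baseline, with multiplicative noise relative to the largest height.
    """
    if not peaks:
        raise ValueError("peak list must be non-empty")
    unknown = {p for p, *_ in peaks} - set(PRODUCT_MZ)
    if unknown:
        raise ValueError(f"unknown product(s): {sorted(unknown)}")
    if meta is None:
        meta = RunMeta()
    rng = np.random.default_rng(seed)
    duration_s = (t_end_c - t_start_c) / ramp_rate_c_min * 60.0
    t_s = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    temp = t_start_c + ramp_rate_c_min * t_s / 60.0

    he_level = 2.0e-9
    i_he = he_level * (1.0 + noise_sd * rng.standard_normal(t_s.size))
    i_he = np.clip(i_he, he_level * 1e-3, None)
    channels: dict[int, np.ndarray] = {meta.internal_standard_mz: i_he}

    by_product: dict[str, list[tuple[float, float, float]]] = {}
    for product, center, height, sigma in peaks:
        by_product.setdefault(product, []).append((center, height, sigma))
    max_height = max(h for _, _, h, _ in peaks)

    scale = 1.0e-10  # product-channel gain, arbitrary units
    for product, plist in by_product.items():
        signal = baseline_level + baseline_slope_per_c * (temp - t_start_c)
        for center, height, sigma in plist:
            signal = signal + height * np.exp(-0.5 * ((temp - center) / sigma) ** 2)
        noisy = signal + noise_sd * max_height * rng.standard_normal(t_s.size)
        channels[PRODUCT_MZ[product]] = np.clip(noisy, 0.0, None) * scale * i_he / he_level

    series = MSTimeSeries(
        run_id=run_id,
        phase=Phase.TPSR,
        time_s=t_s,
        temperature_c=temp,
        channels=channels,
        meta=meta,
    )
    truth = TruthRecord(
        run_id=run_id,
        seed=seed,
        tpsr_peaks=[(p, float(c), float(h), float(s)) for p, c, h, s in peaks],
        noise_sd=noise_sd,
    )
    return series, truth


# ---------------------------------------------------------------------------
# DTT


def k_for_conversion(
    conversion_pct: float,
    background_rate_h: float = 0.05,
    time_h: float = 1.0,
) -> float:
    """Catalytic first-order rate constant giving the stated conversion.

    X = 100 (e^{-k0 t} - e^{-(k+k0) t}) inverted for k.
    """
    resid = math.exp(-background_rate_h * time_h) - conversion_pct / 100.0
    if resid <= 0:
        raise ValueError("conversion unreachable: exceeds the control residual")
    return -math.log(resid) / time_h - background_rate_h


def conversion_for_rate(
    k_h: float,
    background_rate_h: float = 0.05,
    time_h: float = 1.0,
) -> float:
    """Forward map: conversion (%) produced by a catalytic rate constant."""
    return 100.0 * (
        math.exp(-background_rate_h * time_h) - math.exp(-(k_h + background_rate_h) * time_h)
    )


DEFAULT_CALIBRATION = {"slope": 0.0283, "intercept": 0.05}  # A412 per uM / A412
DEFAULT_CAL_CONCS = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)


def gen_dtt_run(
    sample_id: str = "sim-dtt",
    conversion_pct: float = 10.0,
    seed: int = 0,
    positive_conversion_pct: float = 83.75,
    background_rate_h: float = 0.05,
    rate_rel_sd: float = 0.2,
    absorbance_noise: float = 0.002,
    n_replicates: int = 3,
    initial_dtt_um: float = 50.0,
    reaction_volume_ml: float = 6.0,
    enm_concentration_ug_ml: float = 100.0,
    incubation_time_h: float = 1.0,
    dissolution_suspect: bool = False,
    calibration: Mapping[str, float] | None = None,
) -> tuple[DTTRun, TruthRecord]:
    """Synthetic single-endpoint DTT run.

    Per-replicate catalytic rates are k * exp(N(0, s) - s^2/2) (mean-one
    lognormal, ``rate_rel_sd`` = s); the negative control depletes at the
    background rate only.  Absorbances come from the known calibration line
    plus additive Gaussian noise.
    """
    cal = dict(DEFAULT_CALIBRATION if calibration is None else calibration)
    rng = np.random.default_rng(seed)
    t = incubation_time_h
    c0 = initial_dtt_um
    k_cat = k_for_conversion(conversion_pct, background_rate_h, t) if conversion_pct > 0 else 0.0
    k_pos = k_for_conversion(positive_conversion_pct, background_rate_h, t)

    def absorb(conc: np.ndarray) -> np.ndarray:
        a = cal["intercept"] + cal["slope"] * conc
        return np.clip(a + absorbance_noise * rng.standard_normal(conc.shape), 0.0, None)

    k_i = k_cat * np.exp(rate_rel_sd * rng.standard_normal(n_replicates) - 0.5 * rate_rel_sd**2)
    c_sample = c0 * np.exp(-(k_i + background_rate_h) * t)
    c_negative = np.full(n_replicates, c0 * math.exp(-background_rate_h * t))
    c_positive = np.full(n_replicates, c0 * math.exp(-(k_pos + background_rate_h) * t))

    cal_concs = np.array(DEFAULT_CAL_CONCS)
    calibration_points = list(zip(cal_concs.tolist(), absorb(cal_concs).tolist()))

    run = DTTRun(
        sample_id=sample_id,
        absorbance_sample=absorb(c_sample),
        absorbance_negative=absorb(c_negative),
        absorbance_positive=absorb(c_positive),
        calibration_points=calibration_points,
        reaction_volume_ml=reaction_volume_ml,
        initial_dtt_um=c0,
        enm_concentration_ug_ml=enm_concentration_ug_ml,
        incubation_time_h=t,
        dissolution_suspect=dissolution_suspect,
    )
    truth = TruthRecord(
        run_id=sample_id,
        seed=seed,
        dtt_rate_constant_h=k_cat,
        dtt_background_rate_h=background_rate_h,
        true_conversion_pct=conversion_pct,
        true_positive_conversion_pct=positive_conversion_pct,
        noise_sd=absorbance_noise,
    )
    return run, truth


# ---------------------------------------------------------------------------
# eight-material panel


@dataclass(frozen=True)
class MaterialSpec:
    label: str
    bet_m2_per_g: float
    specific_sites_mmol_g: float
    mass_mg: float
    chemisorb_temp_c: float
    tpsr_peaks: tuple[tuple[str, float, float, float], ...]
    oxtof_mean_h: float | None  # None: conversion set directly (dissolution)
    conversion_pct: float | None = None
    dissolution_suspect: bool = False


#: The eight-material proof-of-concept panel.  BET areas and the NM-101 /
#: DT51 / CeO2 site contents are printed values; the remaining site
#: contents are the ones implied by printed gravimetric-to-site-molarity
#: dose pairs.  Peak temperatures follow the stated product maxima; OxTOF
#: tier means follow the stated ratios (top tier = 4x ceria; bottom tier
#: ~3x below ceria).
DEFAULT_PANEL: dict[str, MaterialSpec] = {
    "TiO2 NM-101": MaterialSpec(
        label="TiO2 anatase",
        bet_m2_per_g=225.0,
        specific_sites_mmol_g=2.8,
        mass_mg=100.0,
        chemisorb_temp_c=100.0,
        tpsr_peaks=(("DME", 349.0, 1.0, 28.0), ("HCHO", 300.0, 0.15, 60.0), ("CO2", 410.0, 0.12, 30.0)),
        oxtof_mean_h=0.056,
    ),
    "TiO2 DT51": MaterialSpec(
        label="TiO2 anatase",
        bet_m2_per_g=84.0,
        specific_sites_mmol_g=1.95,
        mass_mg=100.0,
        chemisorb_temp_c=100.0,
        tpsr_peaks=(("DME", 339.0, 0.7, 25.0), ("HCHO", 310.0, 0.12, 55.0), ("CO2", 415.0, 0.1, 30.0)),
        oxtof_mean_h=0.056,
    ),
    "CeO2 NM-211": MaterialSpec(
        label="CeO2",
        bet_m2_per_g=76.0,
        specific_sites_mmol_g=0.7,
        mass_mg=250.0,
        chemisorb_temp_c=100.0,
        tpsr_peaks=(("HCHO", 259.0, 1.0, 20.0), ("DME", 300.0, 0.08, 25.0), ("CO2", 380.0, 0.1, 30.0)),
        oxtof_mean_h=0.195,
    ),
    "CuO-SA": MaterialSpec(
        label="CuO",
        bet_m2_per_g=12.0,
        specific_sites_mmol_g=0.4,
        mass_mg=250.0,
        chemisorb_temp_c=50.0,
        tpsr_peaks=(("CO2", 240.0, 1.0, 25.0), ("HCHO", 230.0, 0.1, 25.0)),
        oxtof_mean_h=0.78,
    ),
    "ZnO NM-110": MaterialSpec(
        label="ZnO",
        bet_m2_per_g=9.0,
        specific_sites_mmol_g=0.3,
        mass_mg=250.0,
        chemisorb_temp_c=50.0,
        tpsr_peaks=(("CO2", 350.0, 1.0, 30.0), ("HCHO", 330.0, 0.08, 35.0)),
        oxtof_mean_h=None,
        conversion_pct=2.0,
        dissolution_suspect=True,
    ),
    "CuFe2O4-SA": MaterialSpec(
        label="CuFe2O4",
        bet_m2_per_g=33.0,
        specific_sites_mmol_g=0.5,
        mass_mg=200.0,
        chemisorb_temp_c=100.0,
        tpsr_peaks=(("CO2", 230.0, 1.0, 25.0), ("HCHO", 245.0, 0.12, 25.0)),
        oxtof_mean_h=0.78,
    ),
    "Fe3O4-SA": MaterialSpec(
        label="Fe3O4",
        bet_m2_per_g=11.0,
        specific_sites_mmol_g=0.2,
        mass_mg=250.0,
        chemisorb_temp_c=100.0,
        tpsr_peaks=(("CO2", 340.0, 1.0, 35.0), ("HCHO", 320.0, 0.12, 40.0)),
        oxtof_mean_h=0.056,
    ),
    "Co3O4-SA": MaterialSpec(
        label="Co3O4",
        bet_m2_per_g=26.0,
        specific_sites_mmol_g=0.3,
        mass_mg=250.0,
        chemisorb_temp_c=100.0,
        tpsr_peaks=(("CO2", 245.0, 1.0, 28.0), ("HCHO", 260.0, 0.1, 30.0)),
        oxtof_mean_h=0.78,
    ),
}


@dataclass
class PanelBundle:
    """A complete synthetic study: sample sheet, MS runs, DTT runs, truth."""

    samples: list[SampleRecord]
    breakthroughs: dict[str, MSTimeSeries]
    blank: MSTimeSeries | None
    tpsr_runs: dict[str, MSTimeSeries]
    dtt_runs: dict[str, DTTRun]
    truth: dict[str, dict[str, TruthRecord]]
    seed: int


def _spec_conversion(spec: MaterialSpec) -> float:
    """Target DTT conversion implied by the per-site rate tier and the
    mixing protocol (0.6 mg in a 6 mL reactor of 50 uM DTT)."""
    if spec.conversion_pct is not None:
        return spec.conversion_pct
    op_mass_mean = spec.oxtof_mean_h * spec.specific_sites_mmol_g * 1e3  # nmol/h/mg
    mass_mg = 100.0 * 6.0 / 1000.0
    return op_mass_mean * 1.0 * mass_mg / (50.0 * 6.0) * 100.0


def gen_panel(
    seed: int = 0,
    config: Mapping[str, MaterialSpec] | None = None,
    include_ms: bool = True,
    noise_sd: float = 0.01,
    drift_amplitude: float = 0.05,
    rate_rel_sd: float = 0.2,
) -> PanelBundle:
    """Generate the full eight-material study bundle.

    ``include_ms=False`` skips the chemisorption/TPSR traces (DTT only),
    for studies of the ranking stage.  Each artifact derives its own child
    seed from ``seed`` so runs are independent but fully reproducible.
    """
    panel = dict(DEFAULT_PANEL if config is None else config)
    for key, spec in panel.items():
        if not isinstance(spec, MaterialSpec):
            raise ValueError(f"unknown material config for {key!r}")
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=3 * len(panel) + 1)

    samples: list[SampleRecord] = []
    breakthroughs: dict[str, MSTimeSeries] = {}
    tpsr_runs: dict[str, MSTimeSeries] = {}
    dtt_runs: dict[str, DTTRun] = {}
    truth: dict[str, dict[str, TruthRecord]] = {}

    from .chemisorption import feed_molar_flow

    meta = RunMeta()
    flow = feed_molar_flow(
        meta.total_flow_ml_min, meta.feed_fraction_ppm, meta.reference_temp_c, meta.pressure_atm
    )

    blank = None
    if include_ms:
        blank, blank_truth = gen_blank(seed=int(child_seeds[-1]), noise_sd=noise_sd,
                                       drift_amplitude=drift_amplitude)
        truth["__blank__"] = {"breakthrough": blank_truth}

    for i, (sid, spec) in enumerate(panel.items()):
        truth[sid] = {}
        samples.append(
            SampleRecord(
                sample_id=sid,
                label=spec.label,
                mass_mg=spec.mass_mg,
                bet_m2_per_g=spec.bet_m2_per_g,
                chemisorb_temp_c=spec.chemisorb_temp_c,
            )
        )
        if include_ms:
            uptake = spec.specific_sites_mmol_g * spec.mass_mg  # umol
            t_b = uptake / flow + 0.3  # + blank dead time
            series, bt_truth = gen_breakthrough(
                run_id=f"{sid}-chemisorption",
                t_b_min=t_b,
                front_width_min=0.5,
                noise_sd=noise_sd,
                drift_amplitude=drift_amplitude,
                seed=int(child_seeds[3 * i]),
                temperature_c=spec.chemisorb_temp_c,
            )
            bt_truth.specific_sites_mmol_g = spec.specific_sites_mmol_g
            breakthroughs[sid] = series
            truth[sid]["breakthrough"] = bt_truth

            tp, tp_truth = gen_tpsr_profile(
                spec.tpsr_peaks,
                seed=int(child_seeds[3 * i + 1]),
                run_id=f"{sid}-tpsr",
                noise_sd=noise_sd,
            )
            tpsr_runs[sid] = tp
            truth[sid]["tpsr"] = tp_truth

        run, dtt_truth = gen_dtt_run(
            sample_id=sid,
            conversion_pct=_spec_conversion(spec),
            seed=int(child_seeds[3 * i + 2]),
            rate_rel_sd=rate_rel_sd,
            dissolution_suspect=spec.dissolution_suspect,
        )
        dtt_truth.specific_sites_mmol_g = spec.specific_sites_mmol_g
        dtt_truth.oxtof_mean_h = spec.oxtof_mean_h
        dtt_runs[sid] = run
        truth[sid]["dtt"] = dtt_truth

    return PanelBundle(
        samples=samples,
        breakthroughs=breakthroughs,
        blank=blank,
        tpsr_runs=tpsr_runs,
        dtt_runs=dtt_runs,
        truth=truth,
        seed=seed,
    )


def write_panel(bundle: PanelBundle, out_dir: str | Path) -> Path:
    """Write the bundle as the package's CSV formats plus ``truth.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_sample_sheet(bundle.samples, out / "sample_sheet.csv")

    def safe(sid: str) -> str:
        return sid.replace(" ", "_").replace("/", "-")

    if bundle.blank is not None:
        write_ms_timeseries(bundle.blank, out / "blank_chemisorption.csv")
    for sid, series in bundle.breakthroughs.items():
        write_ms_timeseries(series, out / f"{safe(sid)}_chemisorption.csv")
    for sid, series in bundle.tpsr_runs.items():
        write_ms_timeseries(series, out / f"{safe(sid)}_tpsr.csv")

    rows = []
    cal_written = False
    for sid, run in bundle.dtt_runs.items():
        for rep, a in enumerate(run.absorbance_sample, start=1):
            rows.append({"sample_id": sid, "role": "sample", "replicate": rep,
                         "absorbance_412": a, "conc_uM": np.nan})
        if not cal_written:
            for rep, a in enumerate(run.absorbance_negative, start=1):
                rows.append({"sample_id": "control", "role": "negative", "replicate": rep,
                             "absorbance_412": a, "conc_uM": np.nan})
            for rep, a in enumerate(run.absorbance_positive, start=1):
                rows.append({"sample_id": "control", "role": "positive", "replicate": rep,
                             "absorbance_412": a, "conc_uM": np.nan})
            for rep, (c, a) in enumerate(run.calibration_points, start=1):
                rows.append({"sample_id": "control", "role": "calibration", "replicate": rep,
                             "absorbance_412": a, "conc_uM": c})
            cal_written = True
    write_dtt_table(pd.DataFrame(rows), out / "dtt_plate.csv")

    payload = {
        "seed": bundle.seed,
        "dissolution_suspect": [
            r.sample_id for r in bundle.dtt_runs.values() if r.dissolution_suspect
        ],
        "truth": {
            sid: {kind: dataclasses.asdict(rec) for kind, rec in kinds.items()}
            for sid, kinds in bundle.truth.items()
        },
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return out
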