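"""End-to-end orchestration: from a study bundle to the per-sample table
and the statistical reactivity ranking.

This is thin glue over the analysis modules; it owns no science of its
own.  The descriptor used for ranking defaults to OxTOF (per-site rate);
dissolution-suspect samples (particles whose DTT signal is carried by
dissolved ions) and below-detection samples are excluded from the ranking.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chemisorption import SiteQuantification, quantify_from_trace
from .core_io import SampleRecord
from .dtt import OPResult, evaluate_op
from .ranking import RankingResult, rank_samples
from .synthetic_data import PanelBundle
from .tpsr import SiteNatureProfile, analyze_tpsr

__all__ = ["PanelAnalysis", "analyze_panel", "DESCRIPTOR_KEYS"]

DESCRIPTOR_KEYS = {"oxtof": "oxtof", "op_mass": "op_mass", "op_area": "op_area"}


@dataclass
class PanelAnalysis:
    table: pd.DataFrame
    quantifications: dict[str, SiteQuantification]
    profiles: dict[str, SiteNatureProfile]
    op_results: dict[str, OPResult]
    ranking: RankingResult | None


def analyze_panel(
    bundle: PanelBundle,
    co2_basic_threshold_c: float = 300.0,
    alpha: float = 0.05,
    descriptor: str = "oxtof",
    run_tpsr: bool = True,
    rank: bool = True,
) -> PanelAnalysis:
    """Analyze every sample of a bundle and rank by the chosen descriptor."""
    if descriptor not in DESCRIPTOR_KEYS:
        raise ValueError(f"descriptor must be one of {sorted(DESCRIPTOR_KEYS)}")

    blank_uptake = 0.0
    if bundle.blank is not None:
        blank_quant = quantify_from_trace(bundle.blank)
        blank_uptake = blank_quant.uptake_umol

    quants: dict[str, SiteQuantification] = {}
    profiles: dict[str, SiteNatureProfile] = {}
    ops: dict[str, OPResult] = {}
    rows: list[dict] = []
    for sample in bundle.samples:
        sid = sample.sample_id
        quant = None
        if sid in bundle.breakthroughs:
            quant = quantify_from_trace(
                bundle.breakthroughs[sid], sample, blank_uptake_umol=blank_uptake
            )
            quants[sid] = quant
        profile = None
        if run_tpsr and sid in bundle.tpsr_runs:
            profile = analyze_tpsr(
                bundle.tpsr_runs[sid], co2_basic_threshold_c=co2_basic_threshold_c
            )
            profiles[sid] = profile
        op = None
        if sid in bundle.dtt_runs:
            op = evaluate_op(
                bundle.dtt_runs[sid],
                sample,
                specific_sites_mmol_g=(quant.specific_sites_mmol_g if quant else None),
            )
            ops[sid] = op
        rows.append(_row(sample, quant, profile, op))

    ranking = None
    if rank and ops:
        groups = {}
        for sid, op in ops.items():
            key = DESCRIPTOR_KEYS[descriptor]
            if op.dissolution_suspect or op.below_detection:
                continue
            if key in op.replicates:
                groups[sid] = op.replicates[key]
        if len(groups) >= 2:
            ranking = rank_samples(groups, alpha=alpha, descriptor=descriptor)
            for row in rows:
                row["letters"] = ranking.letters.get(row["sample_id"], "")

    table = pd.DataFrame(rows)
    return PanelAnalysis(
        table=table, quantifications=quants, profiles=profiles, op_results=ops, ranking=ranking
    )


def _row(
    sample: SampleRecord,
    quant: SiteQuantification | None,
    profile: SiteNatureProfile | None,
    op: OPResult | None,
) -> dict:
    row: dict = {
        "sample_id": sample.sample_id,
        "label": sample.label,
        "mass_mg": sample.mass_mg,
        "bet_m2_per_g": sample.bet_m2_per_g,
    }
    if quant is not None:
        row.update(
            uptake_umol=quant.uptake_umol,
            specific_sites_mmol_g=quant.specific_sites_mmol_g,
            site_density_per_nm2=quant.site_density_per_nm2,
            below_detection=quant.below_detection,
        )
    if profile is not None:
        row.update(
            nature_label=profile.label,
            strength=profile.strength,
            fraction_acid=profile.fraction_acid,
            fraction_redox=profile.fraction_redox,
            fraction_basic=profile.fraction_basic,
            map_x=profile.map_x,
            map_y=profile.map_y,
        )
    if op is not None:
        row.update(
            conversion_pct=op.conversion_pct,
            conversion_sd=op.conversion_sd,
            niog=op.niog,
            niog_sd=op.niog_sd,
            op_mass=op.op_mass,
            op_mass_sd=op.op_mass_sd,
            op_area=op.op_area,
            op_area_sd=op.op_area_sd,
            oxtof=op.oxtof,
            oxtof_sd=op.oxtof_sd,
            dissolution_suspect=op.dissolution_suspect,
        )
    return row
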