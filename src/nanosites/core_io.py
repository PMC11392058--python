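"""Containers and file I/O for instrument and assay artifacts.

All external artifacts are plain delimited text (comma-separated, UTF-8,
``.`` decimal separator, mandatory header row):

* mass-spectrometer time series: ``time_s,temp_C,mz_31,mz_4,...`` with one
  ``mz_<k>`` column per recorded m/z channel, plus a JSON sidecar
  (``<name>.meta.json``) holding run metadata;
* sample sheet: ``sample_id,label,mass_mg,bet_m2_per_g,chemisorb_temp_C``;
* DTT plate table: ``sample_id,role,replicate,absorbance_412,conc_uM`` with
  ``role`` in {sample, negative, positive, calibration}.

Readers never silently drop rows: every row is either parsed or reported
with its line number.  Floats are written with 17 significant digits so a
write/read round trip is bit-exact.
"""
from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "RunMeta",
    "MSTimeSeries",
    "SampleRecord",
    "DTTRun",
    "ParseError",
    "ValidationError",
    "read_ms_timeseries",
    "write_ms_timeseries",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_dtt_table",
    "write_dtt_table",
    "build_dtt_runs",
    "write_report",
]

MS_TIME_COL = "time_s"
MS_TEMP_COL = "temp_C"
MS_CHANNEL_PREFIX = "mz_"
FLOAT_FMT = "%.17g"

DTT_ROLES = ("sample", "negative", "positive", "calibration")


class ParseError(ValueError):
    """A file could not be parsed; the message carries the line number."""


class ValidationError(ValueError):
    """Parsed content violates a contract (invariant or mandatory field)."""


class Phase(str, Enum):
    PRETREAT = "pretreat"
    PURGE = "purge"
    CHEMISORPTION = "chemisorption"
    TPSR = "tpsr"


@dataclass(frozen=True)
class RunMeta:
    """Acquisition metadata shared by the channels of one MS run.

    The defaults are the protocol feed of 100 mL min^-1 of 2000 ppm methanol
    in argon carrying 5% helium; helium (m/z 4) serves as the
    drift-correction internal standard.  Reference conditions for converting
    volumetric to molar flow default to 25 degC and 1 atm.
    """

    total_flow_ml_min: float = 100.0
    feed_fraction_ppm: float = 2000.0
    internal_standard_mz: int = 4
    pressure_atm: float = 1.0
    reference_temp_c: float = 25.0

    def __post_init__(self) -> None:
        if self.total_flow_ml_min <= 0:
            raise ValidationError("total_flow_ml_min must be > 0")
        if self.feed_fraction_ppm < 0:
            raise ValidationError("feed_fraction_ppm must be >= 0")


@dataclass
class MSTimeSeries:
    """One phase of a mass-spectrometer run: time, temperature and per-m/z
    ion currents on a common, strictly increasing time grid."""

    run_id: str
    phase: Phase
    time_s: np.ndarray
    temperature_c: np.ndarray
    channels: dict[int, np.ndarray]
    meta: RunMeta = field(default_factory=RunMeta)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.channels = {int(k): np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.phase = Phase(self.phase)
        n = self.time_s.size
        if n < 2:
            raise ValidationError(f"run {self.run_id!r}: need at least 2 time points")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValidationError(f"run {self.run_id!r}: time_s must be strictly increasing")
        if self.temperature_c.size != n:
            raise ValidationError(f"run {self.run_id!r}: temperature length != time length")
        for mz, arr in self.channels.items():
            if arr.size != n:
                raise ValidationError(f"run {self.run_id!r}: channel mz_{mz} length != time length")
        std = self.meta.internal_standard_mz
        if std not in self.channels:
            raise ValidationError(
                f"run {self.run_id!r}: internal-standard channel mz_{std} missing"
            )

    def __len__(self) -> int:
        return self.time_s.size

    def channel(self, mz: int) -> np.ndarray:
        try:
            return self.channels[int(mz)]
        except KeyError:
            raise ValidationError(
                f"run {self.run_id!r}: channel mz_{int(mz)} not recorded"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        data = {MS_TIME_COL: self.time_s, MS_TEMP_COL: self.temperature_c}
        for mz in sorted(self.channels):
            data[f"{MS_CHANNEL_PREFIX}{mz}"] = self.channels[mz]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class SampleRecord:
    """One nanomaterial sample: identity, loaded mass, BET area and the
    chemisorption temperature used (100 degC, or 50 degC for highly
    reactive materials)."""

    sample_id: str
    label: str
    mass_mg: float
    bet_m2_per_g: float
    chemisorb_temp_c: float = 100.0

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.mass_mg <= 0:
            raise ValidationError(f"sample {self.sample_id!r}: mass_mg must be > 0")
        if self.bet_m2_per_g <= 0:
            raise ValidationError(f"sample {self.sample_id!r}: bet_m2_per_g must be > 0")


@dataclass
class DTTRun:
    """A single-endpoint DTT depletion assay for one sample: replicate
    412 nm absorbances for the sample, the no-particle negative control and
    the H2O2 positive control, plus the DTNB calibration points and the
    mixing-protocol quantities needed to turn conversion into rates."""

    sample_id: str
    absorbance_sample: np.ndarray
    absorbance_negative: np.ndarray
    absorbance_positive: np.ndarray
    calibration_points: list[tuple[float, float]]
    reaction_volume_ml: float = 6.0
    initial_dtt_um: float = 50.0
    enm_concentration_ug_ml: float = 100.0
    incubation_time_h: float = 1.0
    dissolution_suspect: bool = False

    def __post_init__(self) -> None:
        for name in ("absorbance_sample", "absorbance_negative", "absorbance_positive"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if arr.size < 1:
                raise ValidationError(f"{self.sample_id!r}: {name} needs >= 1 replicate")
            if np.any(arr < 0):
                raise ValidationError(f"{self.sample_id!r}: {name} has negative absorbance")
            setattr(self, name, arr)
        if self.initial_dtt_um <= 0:
            raise ValidationError(f"{self.sample_id!r}: initial_dtt_um must be > 0")
        if self.reaction_volume_ml <= 0:
            raise ValidationError(f"{self.sample_id!r}: reaction_volume_ml must be > 0")
        if self.incubation_time_h <= 0:
            raise ValidationError(f"{self.sample_id!r}: incubation_time_h must be > 0")


# ---------------------------------------------------------------------------
# parsing helpers


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        m = re.search(r"line (\d+)", str(exc))
        line = m.group(1) if m else "?"
        raise ParseError(f"{path}: malformed row at line {line}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (no header row)") from exc


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    """Convert one column to float, reporting the 1-based file line of the
    first offending cell (header is line 1).

    Conversion goes through Python's correctly-rounded float parser (not
    ``pd.to_numeric``, whose fast string path can be off by one ulp), so a
    write/read cycle is bit-exact.
    """
    raw = df[col].to_numpy()
    try:
        return raw.astype(float)
    except (TypeError, ValueError):
        pass
    for idx, cell in enumerate(raw):
        if not isinstance(cell, str) or cell == "":
            raise ParseError(f"{path}: missing value in column {col!r} at line {idx + 2}")
        try:
            float(cell)
        except ValueError:
            raise ParseError(
                f"{path}: malformed value {cell!r} in column {col!r} at line {idx + 2}"
            ) from None
    raise ParseError(f"{path}: could not parse column {col!r}")  # pragma: no cover


def _meta_sidecar(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".meta.json")


# ---------------------------------------------------------------------------
# MS time series


def read_ms_timeseries(
    path: str | Path,
    meta: RunMeta | None = None,
    run_id: str | None = None,
    phase: Phase | str | None = None,
) -> MSTimeSeries:
    """Read an MS time-series CSV.

    ``meta``/``run_id``/``phase`` default to the values stored in the JSON
    sidecar written by :func:`write_ms_timeseries`; without a sidecar the
    protocol defaults apply, ``run_id`` falls back to the file stem and
    ``phase`` to chemisorption.
    """
    path = Path(path)
    sidecar = _meta_sidecar(path)
    side: dict = {}
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
    if meta is None:
        meta = RunMeta(**side.get("meta", {}))
    if run_id is None:
        run_id = side.get("run_id", path.stem)
    if phase is None:
        phase = side.get("phase", Phase.CHEMISORPTION)

    df = _read_csv(path)
    for col in (MS_TIME_COL, MS_TEMP_COL):
        if col not in df.columns:
            raise ValidationError(f"{path}: mandatory column {col!r} missing")
    channels: dict[int, np.ndarray] = {}
    for col in df.columns:
        if col.startswith(MS_CHANNEL_PREFIX):
            try:
                mz = int(col[len(MS_CHANNEL_PREFIX):])
            except ValueError:
                raise ValidationError(f"{path}: channel column {col!r} is not mz_<integer>")
            channels[mz] = _numeric(df, col, path)
    if not channels:
        raise ValidationError(f"{path}: no mz_<k> channel columns found")
    values = np.minimum.reduce([np.min(v) for v in channels.values()])
    if values < 0:
        raise ValidationError(f"{path}: negative ion current")
    return MSTimeSeries(
        run_id=run_id,
        phase=Phase(phase),
        time_s=_numeric(df, MS_TIME_COL, path),
        temperature_c=_numeric(df, MS_TEMP_COL, path),
        channels=channels,
        meta=meta,
    )


def write_ms_timeseries(series: MSTimeSeries, path: str | Path) -> Path:
    """Write CSV plus a ``<name>.meta.json`` sidecar with run metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = _meta_sidecar(path)
    sidecar.write_text(
        json.dumps(
            {
                "run_id": series.run_id,
                "phase": series.phase.value,
                "meta": dataclasses.asdict(series.meta),
            },
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    return path


# ---------------------------------------------------------------------------
# sample sheet

SHEET_COLUMNS = ("sample_id", "label", "mass_mg", "bet_m2_per_g", "chemisorb_temp_C")


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    path = Path(path)
    df = _read_csv(path)
    for col in SHEET_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: mandatory field {col!r} missing from sample sheet")
    if df.empty:
        return []
    ids = df["sample_id"].tolist()
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicated sample_id(s): {sorted(dupes)}")
    mass = _numeric(df, "mass_mg", path)
    bet = _numeric(df, "bet_m2_per_g", path)
    temp = _numeric(df, "chemisorb_temp_C", path)
    return [
        SampleRecord(
            sample_id=str(df["sample_id"].iloc[i]),
            label=str(df["label"].iloc[i]),
            mass_mg=float(mass[i]),
            bet_m2_per_g=float(bet[i]),
            chemisorb_temp_c=float(temp[i]),
        )
        for i in range(len(df))
    ]


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "label": [r.label for r in records],
            "mass_mg": [r.mass_mg for r in records],
            "bet_m2_per_g": [r.bet_m2_per_g for r in records],
            "chemisorb_temp_C": [r.chemisorb_temp_c for r in records],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# DTT plate table

DTT_COLUMNS = ("sample_id", "role", "replicate", "absorbance_412")


def read_dtt_table(path: str | Path) -> pd.DataFrame:
    """Read the long-format DTT plate table (one row per replicate).

    Calibration rows additionally carry ``conc_uM``; control rows
    (negative/positive) are shared across samples.
    """
    path = Path(path)
    df = _read_csv(path)
    for col in DTT_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: mandatory field {col!r} missing from DTT table")
    if df.empty:
        return pd.DataFrame(columns=list(DTT_COLUMNS) + ["conc_uM"])
    bad_roles = set(df["role"]) - set(DTT_ROLES)
    if bad_roles:
        raise ValidationError(f"{path}: unknown role(s) {sorted(bad_roles)}")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "role": df["role"].astype(str),
            "replicate": _numeric(df, "replicate", path).astype(int),
            "absorbance_412": _numeric(df, "absorbance_412", path),
        }
    )
    if np.any(out["absorbance_412"].to_numpy() < 0):
        raise ValidationError(f"{path}: negative absorbance")
    if "conc_uM" in df.columns:
        conc = pd.to_numeric(df["conc_uM"].replace("", np.nan), errors="coerce")
        out["conc_uM"] = conc.to_numpy(dtype=float)
        cal = out["role"] == "calibration"
        if cal.any() and out.loc[cal, "conc_uM"].isna().any():
            raise ValidationError(f"{path}: calibration row without conc_uM")
    else:
        if (out["role"] == "calibration").any():
            raise ValidationError(f"{path}: calibration rows require a conc_uM column")
        out["conc_uM"] = np.nan
    return out


def write_dtt_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in list(DTT_COLUMNS) + ["conc_uM"] if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format=FLOAT_FMT)
    return path


def build_dtt_runs(
    df: pd.DataFrame,
    reaction_volume_ml: float = 6.0,
    initial_dtt_um: float = 50.0,
    enm_concentration_ug_ml: float = 100.0,
    incubation_time_h: float = 1.0,
    dissolution_suspect: Iterable[str] = (),
) -> dict[str, DTTRun]:
    """Assemble one :class:`DTTRun` per sample from a plate table, sharing
    the negative/positive controls and calibration points across samples."""
    suspect = set(dissolution_suspect)
    neg = df.loc[df["role"] == "negative", "absorbance_412"].to_numpy(dtype=float)
    pos = df.loc[df["role"] == "positive", "absorbance_412"].to_numpy(dtype=float)
    cal_rows = df[df["role"] == "calibration"]
    calibration = [
        (float(c), float(a))
        for c, a in zip(cal_rows["conc_uM"], cal_rows["absorbance_412"])
    ]
    runs: dict[str, DTTRun] = {}
    sample_rows = df[df["role"] == "sample"]
    for sid, grp in sample_rows.groupby("sample_id", sort=False):
        runs[str(sid)] = DTTRun(
            sample_id=str(sid),
            absorbance_sample=grp["absorbance_412"].to_numpy(dtype=float),
            absorbance_negative=neg,
            absorbance_positive=pos,
            calibration_points=calibration,
            reaction_volume_ml=reaction_volume_ml,
            initial_dtt_um=initial_dtt_um,
            enm_concentration_ug_ml=enm_concentration_ug_ml,
            incubation_time_h=incubation_time_h,
            dissolution_suspect=str(sid) in suspect,
        )
    return runs


# ---------------------------------------------------------------------------
# reports


def write_report(
    results: pd.DataFrame | Sequence[Mapping],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write one machine-readable TSV and one JSON summary.

    Byte-identical output for identical input: fixed column order, fixed
    float formatting, sorted JSON keys, no timestamps.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(list(results))
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_prefix.with_suffix(".tsv")
    js = out_prefix.with_suffix(".json")
    results.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    payload = {
        "n_rows": int(len(results)),
        "columns": list(map(str, results.columns)),
        "rows": json.loads(results.to_json(orient="records", double_precision=10)),
    }
    js.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return tsv, js
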