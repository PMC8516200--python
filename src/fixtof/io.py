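"""Reading traces, writing reports, and run configuration.

Trace CSVs carry one reading per row (``sample_id,time_hr,position_mm,
tof_ns``); the formalin-only calibration reading is either a row with
empty ``time_hr``/``position_mm`` or a JSON sidecar
``{"sample_id": ..., "calibration_tof_ns": ...}``.  All reports are
schema-versioned JSON/CSV and deterministic for identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError
from .monitor import CohortReport, MonitorState
from .stain import QuantConfig, ZoneProfile
from .tof_model import ExpFit, MonitorConfig, TofTrace

SCHEMA_VERSION = "1.0"

TRACE_COLUMNS = ["sample_id", "time_hr", "position_mm", "tof_ns"]


def read_tof_csv(path: str | Path, calibration: float | None = None) -> TofTrace:
    """Load one specimen's TOF trace from CSV.

    Rows may arrive in any order (sorted on load).  Calibration is
    resolved, in order of precedence, from the ``calibration`` argument,
    a row with empty ``time_hr``/``position_mm``, or a ``<path>.json``
    sidecar with a ``calibration_tof_ns`` field.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")

    cal_rows = df[df["time_hr"].isna() & df["position_mm"].isna()]
    data = df.drop(cal_rows.index)
    if calibration is None:
        if len(cal_rows):
            calibration = float(cal_rows["tof_ns"].iloc[0])
        else:
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                calibration = float(json.loads(sidecar.read_text())["calibration_tof_ns"])
    if calibration is None:
        raise ParseError(f"{path.name}: calibration reading missing")
    if data.empty:
        raise ParseError(f"{path.name}: no TOF readings")

    sample_id = str(data["sample_id"].iloc[0])
    grid = data.pivot_table(
        index="time_hr", columns="position_mm", values="tof_ns", aggfunc="mean"
    ).sort_index()
    try:
        return TofTrace(
            sample_id=sample_id,
            times=grid.index.to_numpy(dtype=float),
            positions=grid.columns.to_numpy(dtype=float),
            raw_tof=grid.to_numpy(dtype=float),
            calibration_tof=float(calibration),
        )
    except Exception as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_tof_csv(trace: TofTrace, path: str | Path) -> None:
    """Write a trace (plus its calibration row) in the documented layout."""
    rows = []
    for i, t in enumerate(trace.times):
        for j, p in enumerate(trace.positions):
            v = trace.raw_tof[i, j]
            if np.isfinite(v):
                rows.append((trace.sample_id, t, p, v))
    df = pd.DataFrame(rows, columns=TRACE_COLUMNS)
    cal = pd.DataFrame(
        [(trace.sample_id, np.nan, np.nan, trace.calibration_tof)],
        columns=TRACE_COLUMNS,
    )
    pd.concat([df, cal]).to_csv(path, index=False)


def _fit_record(fit: ExpFit) -> dict:
    return {
        "A_ns": fit.amplitude_A,
        "tau_hr": fit.decay_tau,
        "C_ns": fit.offset_C,
        "cov": [float(v) for v in np.asarray(fit.covariance).ravel()],
        "n": fit.n_points,
        "dof": fit.dof,
    }


def write_report(obj: Any, path: str | Path) -> Path:
    """Serialize a monitor state, zone profile or cohort report.

    MonitorState -> JSON decision report; ZoneProfile -> zone CSV;
    CohortReport -> per-sample CSV (a JSON summary goes to
    ``<stem>.summary.json``).  Output is deterministic and carries
    ``schema_version``.
    """
    path = Path(path)
    if isinstance(obj, MonitorState):
        doc = {
            "schema_version": SCHEMA_VERSION,
            "sample_id": obj.sample_id,
            "n_points": len(obj.times),
            "n_fits": len(obj.fit_history),
            "validated_at_hr": obj.validated_at,
            "predicted_done_at_hr": obj.predicted_done_at,
            "final_fit": _fit_record(obj.fit_history[-1]) if obj.fit_history else None,
            "conditions_final": (
                dict(zip(("past", "present", "future"), obj.condition_flags[-1]))
                if obj.condition_flags
                else None
            ),
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif isinstance(obj, ZoneProfile):
        obj.to_frame().to_csv(path, index=False)
    elif isinstance(obj, CohortReport):
        obj.to_frame().to_csv(path, index=False)
        summary = {
            "schema_version": SCHEMA_VERSION,
            "n_traces": len(obj.records),
            "n_validated": obj.n_validated,
            "n_censored": obj.n_censored,
            "mean_abs_error_hr": obj.mean_abs_error,
            "mean_lead_time_hr": obj.mean_lead_time,
            "mean_validated_at_hr": obj.mean_validated_at,
            "mean_predicted_done_hr": obj.mean_predicted_done,
        }
        path.with_suffix(".summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
    else:
        raise ConfigError(f"cannot serialize object of type {type(obj).__name__}")
    return path


@dataclasses.dataclass
class RunConfig:
    """One structured configuration governing a reproducible run."""

    monitor: MonitorConfig = dataclasses.field(default_factory=MonitorConfig)
    quant: QuantConfig = dataclasses.field(default_factory=QuantConfig)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        mc = dataclasses.asdict(self.monitor)
        qc = dataclasses.asdict(self.quant)
        qc["stain_vectors"] = [float(v) for v in np.asarray(qc["stain_vectors"]).ravel()]
        return {
            "schema_version": SCHEMA_VERSION,
            "monitor": mc,
            "quant": qc,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        doc.pop("schema_version", None)
        known = {"monitor", "quant", "seed", "output_dir", "log_level"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        mc_doc = dict(doc.get("monitor", {}))
        qc_doc = dict(doc.get("quant", {}))
        for sub, fields in (
            (mc_doc, {f.name for f in dataclasses.fields(MonitorConfig)}),
            (qc_doc, {f.name for f in dataclasses.fields(QuantConfig)}),
        ):
            bad = set(sub) - fields
            if bad:
                raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "stain_vectors" in qc_doc:
            qc_doc["stain_vectors"] = np.asarray(qc_doc["stain_vectors"], float).reshape(3, 2)
        return cls(
            monitor=MonitorConfig(**mc_doc),
            quant=QuantConfig(**qc_doc),
            seed=int(doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", ".")),
            log_level=str(doc.get("log_level", "INFO")),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))
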