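"""On-disk formats: HDF5 IQ container, trace/metrics CSVs, results JSON,
YAML configuration, and the run manifest.

HDF5 layout::

    /iq/t1/gate000 ... /iq/t1/gateNNN   complex datasets (slow-time samples)
    /iq/t2/gate000 ...
    /meta                               attributes: f0, prf, half_angle_deg,
                                        gate_depths, c_sound, vessel, seed...

Trace CSV columns: time_s, pressure_mmHg, velocity_cm_s, ecg_event (0/1),
sync_pulse (0/1); per-beat truth goes to a companion ``*_beats.csv`` and
segments/metadata to a ``*_meta.json`` sidecar.  All writers round-trip
exactly (write o read = identity) including NaN sentinels in metrics tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .probes import ProbeGeometry, VesselModel
from .scenarios import ScenarioTraces, TRUTH_COLUMNS
from .synthesize import DualIQRecord

__all__ = [
    "write_iq", "read_iq", "write_traces", "read_traces",
    "write_metrics", "read_metrics", "write_results", "read_results",
    "load_config", "write_manifest", "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# HDF5 IQ container
# ---------------------------------------------------------------------------


def write_iq(record: DualIQRecord, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        meta = f.create_group("meta")
        g = record.geometry
        meta.attrs.update({
            "f0": g.f0, "prf": g.prf, "half_angle_deg": g.half_angle_deg,
            "n_gates": g.n_gates, "gate_depth_min_mm": g.gate_depth_min_mm,
            "gate_depth_max_mm": g.gate_depth_max_mm, "c_sound": g.c_sound,
            "aperture_mm": list(g.aperture_mm), "t0": record.t0,
            "vessel_center_depth_mm": record.vessel.center_depth_mm,
            "vessel_diameter_mm": record.vessel.diameter_mm,
            "vessel_inclination_deg": record.vessel.inclination_deg,
            "vessel_profile_bluntness": record.vessel.profile_bluntness,
            "extra": json.dumps(_sanitize(record.meta)),
        })
        meta.create_dataset("gate_depths_mm", data=record.gate_depths_mm)
        for k in (0, 1):
            grp = f.create_group(f"iq/t{k + 1}")
            for gidx in range(record.iq.shape[1]):
                grp.create_dataset(f"gate{gidx:03d}", data=record.iq[k, gidx])
    return path


def read_iq(path: str | Path) -> DualIQRecord:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
                raise FormatError(
                    f"unsupported IQ container schema in {path.name}")
            meta = f["meta"].attrs
            geometry = ProbeGeometry(
                f0=float(meta["f0"]), half_angle_deg=float(meta["half_angle_deg"]),
                n_gates=int(meta["n_gates"]),
                gate_depth_min_mm=float(meta["gate_depth_min_mm"]),
                gate_depth_max_mm=float(meta["gate_depth_max_mm"]),
                prf=float(meta["prf"]), c_sound=float(meta["c_sound"]),
                aperture_mm=tuple(np.asarray(meta["aperture_mm"], dtype=float)))
            vessel = VesselModel(
                center_depth_mm=float(meta["vessel_center_depth_mm"]),
                diameter_mm=float(meta["vessel_diameter_mm"]),
                inclination_deg=float(meta["vessel_inclination_deg"]),
                profile_bluntness=float(meta["vessel_profile_bluntness"]))
            gate_depths = f["meta/gate_depths_mm"][()]
            gates = sorted(f["iq/t1"].keys())
            n_samples = f[f"iq/t1/{gates[0]}"].shape[0]
            iq = np.empty((2, len(gates), n_samples),
                          dtype=f[f"iq/t1/{gates[0]}"].dtype)
            for k in (0, 1):
                for gidx, name in enumerate(gates):
                    iq[k, gidx] = f[f"iq/t{k + 1}/{name}"][()]
            extra = json.loads(meta.get("extra", "{}"))
            return DualIQRecord(iq=iq, prf=geometry.prf,
                                gate_depths_mm=gate_depths,
                                t0=float(meta["t0"]), geometry=geometry,
                                vessel=vessel, meta=extra)
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read IQ container {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# trace / metrics CSV
# ---------------------------------------------------------------------------


def _event_flags(times: np.ndarray, events: np.ndarray, fs: float) -> np.ndarray:
    flags = np.zeros(len(times), dtype=int)
    if len(events):
        idx = np.round((np.asarray(events) - times[0]) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < len(times))]
        flags[idx] = 1
    return flags


def write_traces(traces: ScenarioTraces, path: str | Path) -> Path:
    path = Path(path)
    fs = traces.fs
    df = pd.DataFrame({
        "time_s": traces.time,
        "pressure_mmHg": traces.pressure,
        "velocity_cm_s": traces.velocity,
        "ecg_event": _event_flags(traces.time, traces.ecg_events, fs),
        "sync_pulse": _event_flags(traces.time, traces.sync_pulses, fs),
    })
    df.to_csv(path, index=False)
    traces.truth.to_csv(_beats_path(path), index=False)
    sidecar = {"segments": [[s, float(a), float(b)] for s, a, b in traces.segments],
               "meta": _sanitize(traces.meta)}
    _meta_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _beats_path(path: Path) -> Path:
    return path.with_name(path.stem + "_beats.csv")


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta.json")


def read_traces(path: str | Path) -> ScenarioTraces:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"time_s", "pressure_mmHg", "velocity_cm_s", "ecg_event",
                    "sync_pulse"}
        if not required.issubset(df.columns):
            raise FormatError(f"trace CSV missing columns {required - set(df.columns)}")
        t = df["time_s"].to_numpy()
        truth = pd.read_csv(_beats_path(path), float_precision="round_trip") \
            if _beats_path(path).exists() \
            else pd.DataFrame(columns=TRUTH_COLUMNS)
        segments, meta = [], {}
        if _meta_path(path).exists():
            sidecar = json.loads(_meta_path(path).read_text())
            segments = [(s, a, b) for s, a, b in sidecar.get("segments", [])]
            meta = sidecar.get("meta", {})
        traces = ScenarioTraces(
            time=t, pressure=df["pressure_mmHg"].to_numpy(),
            velocity=df["velocity_cm_s"].to_numpy(),
            ecg_events=t[df["ecg_event"].to_numpy() == 1],
            sync_pulses=t[df["sync_pulse"].to_numpy() == 1],
            truth=truth, segments=segments, meta=meta)
        traces.validate()
        return traces
    except (pd.errors.ParserError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read trace CSV {path}: {exc}") from exc


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metrics.to_csv(path, index=False)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, OSError) as exc:
        raise FormatError(f"cannot read metrics CSV {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# results JSON, config YAML, manifest
# ---------------------------------------------------------------------------


def _sanitize(obj):
    """Make nested numpy/dataclass content JSON-serializable."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _sanitize(asdict(obj))
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_results(results: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_sanitize(results), indent=1))
    return path


def read_results(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise FormatError(f"cannot read results JSON {path}: {exc}") from exc


def load_config(path: str | Path) -> dict:
    """YAML configuration with sections probe, vessel, scenario, study,
    synthesis, processing, stats (all optional)."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except (yaml.YAMLError, OSError) as exc:
        raise FormatError(f"cannot read config {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError("config root must be a mapping")
    return data


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_sanitize(config), sort_keys=True).encode()).hexdigest()


def write_manifest(path: str | Path, stage: str, seed: int | None,
                   config: dict, inputs: list[str | Path],
                   outputs: list[str | Path]) -> Path:
    """One manifest per CLI run: seed, config hash, versions, and the sha256
    of every input and output file."""
    from . import __version__
    path = Path(path)
    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config),
        "versions": {"carodop": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    path.write_text(json.dumps(manifest, indent=1))
    return path
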