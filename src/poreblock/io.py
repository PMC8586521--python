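"""Plain-text file formats: schemes (YAML/JSON), traces (CSV + JSON sidecar),
release data (CSV) and fit results (JSON).

Units are fixed package-wide — mV, pA, s, s^-1, mol/L, kJ/mol, kT — and are
declared in the column names and sidecar metadata of every file.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd
import yaml

from .betafit import AmplitudeHistogram
from .blockrelease import BlockerReleaseModel, ReleaseData
from .ionflux import KineticScheme, State, Transition
from .simchan import Trace

__all__ = [
    "read_scheme",
    "write_scheme",
    "scheme_to_dict",
    "scheme_from_dict",
    "read_trace",
    "write_trace",
    "read_release_data",
    "write_release_data",
    "write_histogram",
    "read_histogram",
    "write_model",
    "read_model",
    "validate_inputs",
]


# ---------------------------------------------------------------------------
# kinetic schemes
# ---------------------------------------------------------------------------

def scheme_to_dict(scheme: KineticScheme) -> dict:
    return {
        "name": scheme.name,
        "cycle_charge": scheme.cycle_charge,
        "states": [
            {"label": s.label, "sites": sorted(s.sites)} for s in scheme.states
        ],
        "transitions": [
            {
                "from": tr.source,
                "to": tr.target,
                "k0": tr.k0,
                "delta": tr.delta,
                **(
                    {"coupling": {"species": tr.coupling[0], "side": tr.coupling[1]}}
                    if tr.coupling
                    else {}
                ),
            }
            for tr in scheme.transitions
        ],
    }


def scheme_from_dict(d: dict) -> KineticScheme:
    states = tuple(
        State(label=str(s["label"]), sites=frozenset(s.get("sites", ())))
        for s in d["states"]
    )
    transitions = []
    for t in d["transitions"]:
        coupling = None
        if t.get("coupling"):
            coupling = (t["coupling"]["species"], t["coupling"]["side"])
        transitions.append(
            Transition(
                source=str(t["from"]),
                target=str(t["to"]),
                k0=float(t["k0"]),
                delta=float(t.get("delta", 0.0)),
                coupling=coupling,
            )
        )
    return KineticScheme(
        states=states,
        transitions=tuple(transitions),
        cycle_charge=float(d.get("cycle_charge", 1.0)),
        name=str(d.get("name", "")),
    )


def write_scheme(scheme: KineticScheme, path: Union[str, Path]) -> None:
    path = Path(path)
    d = scheme_to_dict(scheme)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))


def read_scheme(path: Union[str, Path]) -> KineticScheme:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return scheme_from_dict(d)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path: Union[str, Path]) -> None:
    """Columnar text (time_s, current_pA) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.current_pA})
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "fs_Hz": trace.fs_Hz,
        "duration_s": trace.duration_s,
        "n_samples": trace.n_samples,
        "units": {"time": "s", "current": "pA"},
        "metadata": _jsonable(trace.metadata),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: Union[str, Path]) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta: Dict = {}
    fs = None
    duration = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        meta = sidecar.get("metadata", {})
        fs = sidecar.get("fs_Hz")
        duration = sidecar.get("duration_s")
    t = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    if duration is None:
        duration = t.size / fs
    return Trace(
        current_pA=df["current_pA"].to_numpy(dtype=float),
        fs_Hz=float(fs),
        duration_s=float(duration),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# release data / histograms / models
# ---------------------------------------------------------------------------

def write_release_data(data: ReleaseData, path: Union[str, Path]) -> None:
    data.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_release_data(path: Union[str, Path]) -> ReleaseData:
    return ReleaseData.from_frame(pd.read_csv(path))


def write_histogram(hist: AmplitudeHistogram, path: Union[str, Path]) -> None:
    hist.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_histogram(path: Union[str, Path]) -> AmplitudeHistogram:
    df = pd.read_csv(path)
    edges = np.append(df["bin_left_pA"].to_numpy(), df["bin_right_pA"].to_numpy()[-1])
    counts = df["count"].to_numpy(dtype=np.int64)
    return AmplitudeHistogram(
        bin_edges=edges, counts=counts, n_total=int(counts.sum())
    )


def write_model(model: BlockerReleaseModel, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_model(path: Union[str, Path]) -> BlockerReleaseModel:
    return BlockerReleaseModel.from_dict(json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: List[Union[str, Path]]) -> List[str]:
    """Schema-check input files; returns a human-readable list of problems
    (empty when everything is well formed).  Never raises on bad content."""
    errors: List[str] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            errors.append(f"{p}: file does not exist")
            continue
        try:
            if p.suffix in (".yaml", ".yml", ".json") and not p.name.endswith(".csv.json"):
                _validate_scheme_file(p, errors)
            elif p.suffix == ".csv":
                _validate_csv_file(p, errors)
            else:
                errors.append(f"{p}: unrecognized input type")
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            errors.append(f"{p}: {exc}")
    return errors


def _validate_scheme_file(p: Path, errors: List[str]) -> None:
    text = p.read_text()
    d = yaml.safe_load(text) if p.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(d, dict) or "states" not in d or "transitions" not in d:
        errors.append(f"{p}: not a scheme file (needs 'states' and 'transitions')")
        return
    labels = {str(s.get("label")) for s in d["states"]}
    for t in d["transitions"]:
        src, tgt = str(t.get("from")), str(t.get("to"))
        if src not in labels or tgt not in labels:
            errors.append(f"{p}: transition {src}->{tgt} references unknown state")
        k0 = t.get("k0")
        if k0 is None or (isinstance(k0, (int, float)) and k0 < 0):
            errors.append(f"{p}: transition {src}->{tgt} has invalid rate {k0}")


def _validate_csv_file(p: Path, errors: List[str]) -> None:
    df = pd.read_csv(p)
    cols = set(df.columns)
    if {"time_s", "current_pA"} <= cols:
        t = df["time_s"].to_numpy()
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            errors.append(
                f"{p}: time column not strictly increasing at row {int(bad[0]) + 1}"
            )
    elif {"voltage_mV", "koff_per_s"} <= cols:
        neg = df.index[df["koff_per_s"] <= 0]
        if len(neg):
            errors.append(f"{p}: non-positive koff at row {int(neg[0])}")
        if "gsd" in cols:
            badg = df.index[df["gsd"] < 1]
            if len(badg):
                errors.append(f"{p}: geometric SD < 1 at row {int(badg[0])}")
    elif {"bin_left_pA", "bin_right_pA", "count"} <= cols:
        if np.any(df["count"].to_numpy() < 0):
            errors.append(f"{p}: negative histogram count")
    else:
        errors.append(f"{p}: unrecognized CSV columns {sorted(cols)}")
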