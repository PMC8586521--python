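"""End-to-end pipeline: synthetic recordings -> histogram fits -> koff(V) ->
occupancy -> release-model fit -> asymmetric prediction.

The pipeline emulates the full analysis workflow on generated data.  The
blocker release rate used to generate the recordings follows
kBO(V) = a + b * P(S4, V) with P(S4) from the blocked hopping scheme, so the
final release-model fit closes the loop against known ground truth.  All
randomness derives from the single seed in the configuration; rerunning a
config reproduces every numeric output byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import yaml

from . import __version__
from . import io as pio
from .betafit import (
    amplitude_histogram,
    blocking_rate_init,
    extract_koff,
    fit_histogram,
    open_peak_window,
)
from .blockrelease import delta_delta_G, fit_release, predict_asymmetric
from .ionflux import (
    KineticScheme,
    apply_block,
    kcv_like_scheme,
    occupancy_vs_voltage,
    symmetric_kcl_conditions,
)
from .simchan import FixtureConfig, GatingScheme, make_fixture_set

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records partial completion."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (seeds are always explicit)."""

    seed: int
    scheme: Union[str, KineticScheme] = "builtin:kcv-like"
    kcl_mM: float = 100.0
    voltages_mV: List[float] = field(default_factory=lambda: [-120.0, -80.0, 80.0, 120.0])
    tpra_mM: List[float] = field(default_factory=lambda: [0.5])
    duration_s: float = 10.0
    conductance_pS: float = 55.0
    konO_per_M_s: float = 2.0e8
    fc_Hz: float = 1000.0
    fs_Hz: float = 5000.0
    oversampling: int = 20
    noise_sd_pA: float = 0.8
    release_a_per_s: float = 31400.0
    release_b_per_s: float = 378600.0
    fit_maxfev: int = 100
    fit_restarts: int = 1
    asymmetric_external_kcl_mM: float = 500.0
    intrinsic: Dict[str, float] = field(default_factory=dict)

    def resolve_scheme(self) -> KineticScheme:
        if isinstance(self.scheme, KineticScheme):
            return self.scheme
        if self.scheme == "builtin:kcv-like":
            return kcv_like_scheme()
        path = Path(self.scheme)
        if not path.exists():
            raise FileNotFoundError(f"scheme file not found: {path}")
        return pio.read_scheme(path)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(self.scheme, KineticScheme):
            d["scheme"] = pio.scheme_to_dict(self.scheme)
        return d


def load_config(path: Union[str, Path]) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "seed" not in raw:
        raise ValueError("pipeline config must set an explicit seed")
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # YAML 1.1 parses exponents without a sign ("2e8") as strings; coerce
    for key, value in raw.items():
        if fields[key].type == "float" and isinstance(value, str):
            raw[key] = float(value)
    return PipelineConfig(**raw)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: List[Dict] = field(default_factory=list)
    files: List[str] = field(default_factory=list)
    completed: bool = False
    started_at: float = 0.0
    finished_at: float = 0.0

    def record(self, name: str, outputs: List[str]) -> None:
        self.stages.append({"stage": name, "outputs": outputs})
        self.files.extend(outputs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: Union[str, Path]) -> RunManifest:
    """Execute all stages; deterministic given the config seed.

    Raises :class:`PipelineError` on stage failure after writing a manifest
    that records partial completion.  Configuration problems (e.g. a missing
    scheme file) are raised before any output is written.
    """
    # -- validation before any output ------------------------------------
    scheme = config.resolve_scheme()
    if not config.voltages_mV:
        raise ValueError("pipeline needs at least one voltage")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(config),
        seed=config.seed,
        started_at=time.time(),
    )
    manifest_path = out / "manifest.json"

    def _finish(ok: bool):
        manifest.completed = ok
        manifest.finished_at = time.time()
        manifest_path.write_text(json.dumps(manifest.to_dict(), indent=1))

    try:
        _run_stages(config, scheme, out, manifest)
    except Exception as exc:
        _finish(False)
        raise PipelineError(f"pipeline stage failed: {exc}") from exc
    _finish(True)
    return manifest


def _run_stages(config: PipelineConfig, scheme: KineticScheme,
                out: Path, manifest: RunManifest) -> None:
    cond = symmetric_kcl_conditions(kcl_mM=config.kcl_mM)
    blocked = apply_block(scheme)
    grid = np.arange(-160.0, 161.0, 10.0)

    # stage 1: occupancy profiles ----------------------------------------
    prof_open = occupancy_vs_voltage(scheme, cond, grid)
    prof_blocked = occupancy_vs_voltage(blocked, cond, grid)
    f_open, f_blocked = out / "occupancy_open.csv", out / "occupancy_blocked.csv"
    prof_open.to_frame().to_csv(f_open, index=False, float_format="%.12g")
    prof_blocked.to_frame().to_csv(f_blocked, index=False, float_format="%.12g")
    manifest.record("occupancy", [f_open.name, f_blocked.name])

    p_s4 = prof_blocked.site_interpolator("S4")
    a_true, b_true = config.release_a_per_s, config.release_b_per_s

    # stage 2: synthetic recordings --------------------------------------
    base = GatingScheme(**config.intrinsic) if config.intrinsic else GatingScheme()
    fixcfg = FixtureConfig(
        voltages_mV=tuple(config.voltages_mV),
        tpra_mM=tuple([0.0] + [c for c in config.tpra_mM if c > 0]),
        duration_s=config.duration_s,
        seed=config.seed,
        conductance_pS=config.conductance_pS,
        noise_sd_pA=config.noise_sd_pA,
        fc_Hz=config.fc_Hz,
        fs_Hz=config.fs_Hz,
        oversampling=config.oversampling,
        konO=config.konO_per_M_s,
        kbo=lambda v: a_true + b_true * float(p_s4(v)),
        base_scheme=base,
    )
    fixtures = make_fixture_set(fixcfg)
    tdir = out / "traces"
    tdir.mkdir(exist_ok=True)
    tfiles = []
    for k, trace in enumerate(fixtures.traces):
        entry = fixtures.manifest["conditions"][k]
        fname = tdir / f"trace_v{entry['voltage_mV']:+.0f}mV_c{entry['tpra_mM']:g}mM.csv"
        pio.write_trace(trace, fname)
        tfiles.append(f"traces/{fname.name}")
    (out / "fixture_manifest.json").write_text(
        json.dumps(fixtures.manifest, indent=1)
    )
    manifest.record("simulate", tfiles + ["fixture_manifest.json"])

    # stage 3: histogram fits --------------------------------------------
    entries = fixtures.manifest["conditions"]
    from .simchan import AcquisitionSettings

    i_true_by_voltage: Dict[float, float] = {}
    fit_records = []
    blocker_fits = []
    # control traces first: determine I_true per voltage
    for trace, entry in zip(fixtures.traces, entries):
        if entry["tpra_mM"] != 0.0:
            continue
        settings = AcquisitionSettings(
            fc_Hz=config.fc_Hz, fs_Hz=config.fs_Hz,
            noise_sd_pA=config.noise_sd_pA, oversampling=config.oversampling,
            duration_s=config.duration_s, seed=entry["seed"],
        )
        template = GatingScheme(
            i_true_pA=1.2 * entry["i_true_pA"] if entry["i_true_pA"] else 1.0,
            tpra_mM=0.0, konO=config.konO_per_M_s,
            **{k: entry["intrinsic"][k] for k in entry["intrinsic"]},
        )
        hist = amplitude_histogram(trace)
        fit = fit_histogram(
            hist, template, settings, free=["i_true_pA"],
            seed=config.seed + 1, maxfev=config.fit_maxfev,
            restarts=config.fit_restarts,
            window_pA=open_peak_window(entry["i_true_pA"], config.noise_sd_pA),
        )
        i_true_by_voltage[entry["voltage_mV"]] = fit.params["i_true_pA"]
        fit_records.append(fit.to_dict())
    # blocker traces: fit kOB, kBO with I_true fixed from control
    for trace, entry in zip(fixtures.traces, entries):
        if entry["tpra_mM"] == 0.0:
            continue
        settings = AcquisitionSettings(
            fc_Hz=config.fc_Hz, fs_Hz=config.fs_Hz,
            noise_sd_pA=config.noise_sd_pA, oversampling=config.oversampling,
            duration_s=config.duration_s, seed=entry["seed"],
        )
        v = entry["voltage_mV"]
        template = GatingScheme(
            i_true_pA=i_true_by_voltage.get(v, entry["i_true_pA"]),
            tpra_mM=entry["tpra_mM"], konO=config.konO_per_M_s,
            kBO=1.0e5,
            **{k: entry["intrinsic"][k] for k in entry["intrinsic"]},
        )
        hist = amplitude_histogram(trace)
        init = blocking_rate_init(hist, template)
        fit = fit_histogram(
            hist, template, settings, free=init,
            seed=config.seed + 2, maxfev=config.fit_maxfev,
            restarts=config.fit_restarts,
            window_pA=open_peak_window(template.i_true_pA, config.noise_sd_pA),
        )
        blocker_fits.append(fit)
        fit_records.append(fit.to_dict())
    f_fits = out / "gating_fits.json"
    f_fits.write_text(json.dumps(fit_records, indent=1))
    manifest.record("fit-gating", [f_fits.name])

    # stage 4: koff(V) ----------------------------------------------------
    release, diagnostics = extract_koff(blocker_fits)
    f_rel = out / "release.csv"
    pio.write_release_data(release, f_rel)
    (out / "koff_diagnostics.json").write_text(json.dumps(diagnostics, indent=1))
    manifest.record("extract-koff", [f_rel.name, "koff_diagnostics.json"])

    # stage 5: release-model fit ------------------------------------------
    model = fit_release(release, p_s4)
    f_model = out / "release_model.json"
    pio.write_model(model, f_model)
    manifest.record("fit-release", [f_model.name])

    # stage 6: asymmetric prediction --------------------------------------
    cond_asym = symmetric_kcl_conditions(
        kcl_mM=config.kcl_mM, external_kcl_mM=config.asymmetric_external_kcl_mM
    )
    pred = predict_asymmetric(model, scheme, cond_asym, grid)
    f_pred = out / "prediction_asymmetric.csv"
    pred.to_frame().to_csv(f_pred, index=False, float_format="%.12g")
    manifest.record("predict", [f_pred.name])

    # summary --------------------------------------------------------------
    ddg_kt, ddg_kj = delta_delta_G(model)
    summary = {
        "a_per_s": model.a,
        "b_per_s": model.b,
        "c_per_s": model.c,
        "ddG_kT": ddg_kt,
        "ddG_kJmol": ddg_kj,
        "truth": {"a_per_s": a_true, "b_per_s": b_true},
        "n_koff_points": len(release),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    manifest.record("summary", ["summary.json"])
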