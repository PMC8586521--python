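"""Synthetic single-channel current recordings.

Channel gating is a continuous-time Markov chain over the states O (open,
conducting I_true), three intrinsic closed states F, M, S of increasingly
long dwell times, and a blocked state B entered from O at the
pseudo-first-order rate kOB = konO * [blocker] and left at kBO.  The blocker
interacts only with the open state, so B connects exclusively to O.

An ideal recording is the piecewise-constant current I_true * 1[state == O].
A real recording passes through the acquisition chain, which this module
emulates: the ideal current is integrated area-preservingly onto an
oversampled grid (sub-sample dwells contribute their exact area), convolved
with a discretized 4-pole Bessel low-pass (-3 dB at fc, unit DC gain,
zero-order-hold discretization at the oversampled rate), decimated to the
sampling rate, and overlaid with white Gaussian baseline noise.  Blocking/gating faster than
the filter bandwidth is thereby attenuated into "excess noise" around a
reduced apparent current — the signal that amplitude-histogram analysis
exploits.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np
from scipy import signal

from . import _kernels
from .ionflux import KineticScheme, State, Transition

__all__ = [
    "GATING_STATES",
    "GatingScheme",
    "AcquisitionSettings",
    "GatingEvents",
    "Trace",
    "FixtureConfig",
    "FixtureSet",
    "AbsorbingStateError",
    "simulate_gating",
    "render_trace",
    "simulate_recording",
    "make_fixture_set",
    "bessel_coeffs",
    "markov_occupancy",
    "markov_dwell_stats",
]

GATING_STATES = ("O", "F", "M", "S", "B")

_MAX_CHUNK_EVENTS = 4_000_000


class AbsorbingStateError(RuntimeError):
    """The simulation entered a state with zero exit rate."""


def _seed32(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1)) + 1


@dataclass(frozen=True)
class GatingScheme:
    """O/F/M/S/B gating scheme of a blocked channel.

    Rates in s^-1 except konO (s^-1 M^-1); blocker concentration in mM.
    ``kOB_override`` fixes kOB directly (used when kOB itself is a fit
    parameter); otherwise kOB = konO * [blocker in M].
    """

    i_true_pA: float = 6.6
    kOF: float = 1500.0
    kFO: float = 60_000.0
    kOM: float = 40.0
    kMO: float = 1200.0
    kOS: float = 1.5
    kSO: float = 15.0
    konO: float = 2.0e8
    kBO: float = 1.0e5
    tpra_mM: float = 0.0
    kOB_override: Optional[float] = None

    def __post_init__(self):
        for name in ("kOF", "kFO", "kOM", "kMO", "kOS", "kSO", "konO", "kBO", "tpra_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kOB_override is not None and self.kOB_override < 0:
            raise ValueError("kOB_override must be non-negative")

    @property
    def kOB(self) -> float:
        if self.kOB_override is not None:
            return self.kOB_override
        return self.konO * self.tpra_mM * 1e-3

    @property
    def labels(self) -> Tuple[str, ...]:
        return GATING_STATES

    def rate_matrix(self) -> np.ndarray:
        """Generator matrix in the state order O, F, M, S, B."""
        Q = np.zeros((5, 5))
        O, F, M, S, B = range(5)
        Q[O, F], Q[F, O] = self.kOF, self.kFO
        Q[O, M], Q[M, O] = self.kOM, self.kMO
        Q[O, S], Q[S, O] = self.kOS, self.kSO
        Q[O, B], Q[B, O] = self.kOB, self.kBO
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def current_levels(self) -> np.ndarray:
        """Per-state conductance levels (only O conducts)."""
        levels = np.zeros(5)
        levels[0] = self.i_true_pA
        return levels

    def with_rates(self, **rates) -> "GatingScheme":
        """Copy with rate (or ``i_true_pA``/``kOB``) overrides; ``kOB=x``
        sets ``kOB_override``."""
        if "kOB" in rates:
            rates["kOB_override"] = rates.pop("kOB")
        return replace(self, **rates)

    def as_kinetic_scheme(self) -> KineticScheme:
        """View as a generic kinetic scheme (for steady-state cross-checks)."""
        states = tuple(State(lab) for lab in GATING_STATES)
        pairs = [
            ("O", "F", self.kOF), ("F", "O", self.kFO),
            ("O", "M", self.kOM), ("M", "O", self.kMO),
            ("O", "S", self.kOS), ("S", "O", self.kSO),
            ("O", "B", self.kOB), ("B", "O", self.kBO),
        ]
        transitions = tuple(Transition(a, b, k) for a, b, k in pairs if k > 0)
        return KineticScheme(states=states, transitions=transitions, name="gating")


@dataclass(frozen=True)
class AcquisitionSettings:
    """Filter, sampling, noise and duration of the emulated recording."""

    fc_Hz: float = 1000.0
    filter_order: int = 4
    fs_Hz: float = 5000.0
    noise_sd_pA: float = 0.8
    oversampling: int = 20
    duration_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.oversampling < 10:
            raise ValueError("oversampling factor must be >= 10")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs_Hz <= 2 * self.fc_Hz:
            warnings.warn(
                f"sampling rate {self.fs_Hz} Hz does not exceed twice the "
                f"filter cutoff {self.fc_Hz} Hz",
                stacklevel=2,
            )

    @property
    def oversampled_rate_Hz(self) -> float:
        return self.fs_Hz * self.oversampling

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_Hz))


@dataclass(frozen=True)
class GatingEvents:
    """Dwell sequence of a gating simulation; events tile [0, duration]."""

    state_index: np.ndarray
    t_entry: np.ndarray
    dwell: np.ndarray
    labels: Tuple[str, ...]
    duration_s: float

    @property
    def n_events(self) -> int:
        return self.state_index.size

    def state_fractions(self) -> np.ndarray:
        """Time-weighted occupancy fraction of each state."""
        out = np.zeros(len(self.labels))
        np.add.at(out, self.state_index, self.dwell)
        return out / out.sum()

    def visits(self, label: str) -> int:
        return int(np.count_nonzero(self.state_index == self.labels.index(label)))


@dataclass(frozen=True)
class Trace:
    """Sampled, filtered, noisy single-channel current record."""

    current_pA: np.ndarray
    fs_Hz: float
    duration_s: float
    metadata: Dict = field(default_factory=dict)
    events: Optional[GatingEvents] = None

    @property
    def n_samples(self) -> int:
        return self.current_pA.size

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_Hz


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

def _embedded_chain(Q: np.ndarray):
    exit_rates = -np.diag(Q).copy()
    n = Q.shape[0]
    cum = np.zeros((n, n))
    for i in range(n):
        row = Q[i].copy()
        row[i] = 0.0
        if exit_rates[i] > 0:
            cum[i] = np.cumsum(row / exit_rates[i])
        else:
            cum[i] = 1.0
    return exit_rates, cum


def simulate_gating(
    scheme: GatingScheme,
    duration_s: float,
    seed: Union[int, np.random.SeedSequence],
    start: str = "O",
    absorbing: str = "error",
) -> GatingEvents:
    """Exact stochastic simulation of the gating chain for the given duration.

    Dwell times are exponential with the state's total exit rate; the
    successor is drawn proportionally to the outgoing rates.  Reproducible
    given the seed.  ``absorbing`` controls what happens when a state with
    zero exit rate is entered: ``"error"`` raises (naming the state),
    ``"hold"`` keeps the chain there for the remaining duration (meaningful
    for degenerate schemes such as a channel that never closes).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    Q = scheme.rate_matrix()
    return _simulate_chain(Q, GATING_STATES, duration_s, seed,
                           GATING_STATES.index(start), absorbing)


def _simulate_chain(Q, labels, duration_s, seed, start_index,
                    absorbing: str = "error") -> GatingEvents:
    if absorbing not in ("error", "hold"):
        raise ValueError("absorbing must be 'error' or 'hold'")
    exit_rates, cum = _embedded_chain(np.asarray(Q, dtype=float))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chunks = []
    s, t = start_index, 0.0
    while t < duration_s:
        ss, child = ss.spawn(2)
        out = _kernels._ssa_chunk(
            exit_rates, cum, s, t, float(duration_s),
            _MAX_CHUNK_EVENTS, _seed32(child),
        )
        states, t_entry, dwell, s, t, flag = out
        chunks.append((states, t_entry, dwell))
        if flag:
            if absorbing == "error":
                raise AbsorbingStateError(
                    f"state {labels[s]} has zero exit rate (absorbing)"
                )
            chunks.append((
                np.array([s], dtype=np.int64),
                np.array([t]),
                np.array([duration_s - t]),
            ))
            break
        if states.size == 0:
            break
    return GatingEvents(
        state_index=np.concatenate([c[0] for c in chunks]),
        t_entry=np.concatenate([c[1] for c in chunks]),
        dwell=np.concatenate([c[2] for c in chunks]),
        labels=tuple(labels),
        duration_s=float(duration_s),
    )


def markov_occupancy(
    Q: np.ndarray,
    n_events: int,
    seed: int,
    n_batches: int = 20,
    start: int = 0,
):
    """Monte-Carlo estimate of stationary occupancy of an arbitrary generator.

    Returns (fractions, standard errors) where the SE comes from batch means
    over ``n_batches`` consecutive segments of the single long run.
    """
    exit_rates, cum = _embedded_chain(np.asarray(Q, dtype=float))
    occ, flag = _kernels._occupancy_batches(
        exit_rates, cum, start, int(n_events), int(n_batches), int(seed) % (2**31 - 1) + 1
    )
    if flag:
        raise AbsorbingStateError("chain entered an absorbing state")
    mean = occ.mean(axis=0)
    se = occ.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return mean, se


def markov_dwell_stats(Q: np.ndarray, n_events: int, seed: int, start: int = 0):
    """Per-state (mean dwell, visit count) over an SSA run of n_events."""
    exit_rates, cum = _embedded_chain(np.asarray(Q, dtype=float))
    total, visits, flag = _kernels._dwell_stats(
        exit_rates, cum, start, int(n_events), int(seed) % (2**31 - 1) + 1
    )
    if flag:
        raise AbsorbingStateError("chain entered an absorbing state")
    with np.errstate(invalid="ignore"):
        mean_dwell = np.where(visits > 0, total / np.maximum(visits, 1), np.nan)
    return mean_dwell, visits


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def bessel_coeffs(settings: AcquisitionSettings) -> Tuple[np.ndarray, np.ndarray]:
    """Discrete Bessel low-pass (b, a) at the oversampled rate.

    The analog prototype (-3 dB at fc, unit DC gain) is discretized by
    zero-order hold: the rendered input is piecewise constant over oversample
    bins, for which the ZOH-discretized filter reproduces the analog jump
    response exactly at the sample instants (a bilinear transform would leave
    a rise-time error of order 1/oversampling on each jump).
    """
    b, a = signal.bessel(
        settings.filter_order,
        2.0 * np.pi * settings.fc_Hz,
        btype="low",
        analog=True,
        norm="mag",
    )
    bz, az, _ = signal.cont2discrete((b, a), 1.0 / settings.oversampled_rate_Hz,
                                     method="zoh")
    return np.atleast_1d(np.squeeze(bz)), np.atleast_1d(np.squeeze(az))


def render_trace(
    events: GatingEvents,
    scheme: GatingScheme,
    settings: AcquisitionSettings,
    noise_seed: Optional[Union[int, np.random.SeedSequence]] = None,
) -> Trace:
    """Acquisition-chain rendering of a gating event sequence.

    Oversampled area-preserving integration of the ideal current, Bessel
    filtering, decimation to the sampling rate, then white Gaussian baseline
    noise at the sampling rate.  ``noise_seed`` defaults to
    ``settings.seed``.
    """
    n_samples = settings.n_samples
    ovs = settings.oversampling
    n_bins = n_samples * ovs
    dt = 1.0 / settings.oversampled_rate_Hz
    meta_warnings: List[str] = []

    Q = scheme.rate_matrix()
    max_exit = float(-np.diag(Q).min())
    if max_exit > 0 and 1.0 / max_exit < 2 * dt:
        meta_warnings.append(
            f"shortest mean dwell {1e6 / max_exit:.2f} us is below two "
            f"oversample intervals ({2e6 * dt:.2f} us); sub-bin events are "
            "integrated area-preservingly but individual excursions are not resolved"
        )

    ideal = _kernels._bin_average(
        events.state_index, events.t_entry, events.dwell,
        scheme.current_levels(), n_bins, dt,
    )
    bz, az = bessel_coeffs(settings)
    filtered = signal.lfilter(bz, az, ideal)
    sampled = np.ascontiguousarray(filtered[::ovs][:n_samples])

    if noise_seed is None:
        noise_seed = settings.seed
    rng = np.random.default_rng(noise_seed)
    if settings.noise_sd_pA > 0:
        sampled = sampled + rng.normal(0.0, settings.noise_sd_pA, sampled.size)

    metadata = {
        "i_true_pA": scheme.i_true_pA,
        "tpra_mM": scheme.tpra_mM,
        "kOB_per_s": scheme.kOB,
        "kBO_per_s": scheme.kBO,
        "fc_Hz": settings.fc_Hz,
        "filter_order": settings.filter_order,
        "fs_Hz": settings.fs_Hz,
        "oversampling": settings.oversampling,
        "noise_sd_pA": settings.noise_sd_pA,
        "duration_s": settings.duration_s,
        "seed": settings.seed,
        "warnings": meta_warnings,
    }
    return Trace(
        current_pA=sampled,
        fs_Hz=settings.fs_Hz,
        duration_s=settings.duration_s,
        metadata=metadata,
        events=events,
    )


def simulate_recording(
    scheme: GatingScheme,
    settings: AcquisitionSettings,
    seed: Optional[Union[int, np.random.SeedSequence]] = None,
    absorbing: str = "hold",
) -> Trace:
    """Gating simulation plus rendering in one step, fully seeded.

    The seed (default ``settings.seed``) is split into independent gating and
    baseline-noise streams.  A state without exit holds for the remaining
    duration (a trace of a channel that never gates is still a valid
    recording).
    """
    if seed is None:
        seed = settings.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gating_ss, noise_ss = ss.spawn(2)
    events = simulate_gating(scheme, settings.duration_s, gating_ss,
                             absorbing=absorbing)
    return render_trace(events, scheme, settings, noise_seed=noise_ss)


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    """Condition grid for a deterministic set of synthetic recordings.

    ``kbo`` may be a constant or a callable kBO(voltage_mV); ``i_true`` is by
    default the linear conductance model conductance_pS * V.
    """

    voltages_mV: Tuple[float, ...] = (-160, -120, -80, -40, 40, 80, 120, 160)
    tpra_mM: Tuple[float, ...] = (0.0, 0.1, 1.0)
    duration_s: float = 60.0
    seed: int = 0
    conductance_pS: float = 55.0
    noise_sd_pA: float = 0.8
    fc_Hz: float = 1000.0
    fs_Hz: float = 5000.0
    oversampling: int = 20
    konO: float = 2.0e8
    kbo: Union[float, Callable[[float], float]] = 1.0e5
    base_scheme: GatingScheme = GatingScheme()


@dataclass(frozen=True)
class FixtureSet:
    traces: Tuple[Trace, ...]
    manifest: Dict


def make_fixture_set(config: FixtureConfig) -> FixtureSet:
    """Simulate every (voltage, concentration) condition of the grid.

    The manifest records the generating parameters of every trace (ground
    truth for recovery tests) and the per-trace seeds derived
    deterministically from the master seed.
    """
    conditions = [(v, c) for v in config.voltages_mV for c in config.tpra_mM]
    children = np.random.SeedSequence(config.seed).spawn(len(conditions)) if conditions else []
    traces = []
    entries = []
    for (v, conc), child in zip(conditions, children):
        kbo = float(config.kbo(v)) if callable(config.kbo) else float(config.kbo)
        scheme = config.base_scheme.with_rates(
            i_true_pA=config.conductance_pS * v * 1e-3,
            konO=config.konO,
            kBO=kbo,
            tpra_mM=conc,
        )
        trace_seed = _seed32(child)
        settings = AcquisitionSettings(
            fc_Hz=config.fc_Hz,
            fs_Hz=config.fs_Hz,
            noise_sd_pA=config.noise_sd_pA,
            oversampling=config.oversampling,
            duration_s=config.duration_s,
            seed=trace_seed,
        )
        trace = simulate_recording(scheme, settings)
        trace.metadata["voltage_mV"] = v
        traces.append(trace)
        entries.append(
            {
                "voltage_mV": v,
                "tpra_mM": conc,
                "duration_s": config.duration_s,
                "seed": trace_seed,
                "i_true_pA": scheme.i_true_pA,
                "kOB_per_s": scheme.kOB,
                "kBO_per_s": scheme.kBO,
                "konO_per_M_s": scheme.konO,
                "intrinsic": {
                    "kOF": scheme.kOF, "kFO": scheme.kFO,
                    "kOM": scheme.kOM, "kMO": scheme.kMO,
                    "kOS": scheme.kOS, "kSO": scheme.kSO,
                },
            }
        )
    manifest = {
        "seed": config.seed,
        "settings": {
            "fc_Hz": config.fc_Hz,
            "fs_Hz": config.fs_Hz,
            "filter_order": 4,
            "oversampling": config.oversampling,
            "noise_sd_pA": config.noise_sd_pA,
        },
        "conditions": entries,
    }
    return FixtureSet(traces=tuple(traces), manifest=manifest)
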