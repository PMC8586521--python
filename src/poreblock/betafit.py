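"""Amplitude-histogram analysis of filtered single-channel recordings.

Blocking and gating faster than the recording filter bandwidth cannot be
resolved event by event, but the attenuated transitions leave "excess noise"
that broadens the open-channel peak of the amplitude histogram into a
non-Gaussian (extended-beta-family) shape.  Those hidden rate constants are
recovered by matched simulation: candidate parameters are turned into a
predicted histogram by simulating a time series through exactly the same
filter and baseline-noise chain as the measurement, and a simplex
(Nelder-Mead) search minimizes a chi-squared distance between measured and
predicted histograms.  Common random numbers (one fixed seed per fit) make
the simulation-based objective deterministic and smooth enough for the
simplex.

The release rate kBO extracted per voltage and blocker concentration is the
open-channel blocker dissociation rate koff; pooling it across
concentrations (release does not depend on blocker concentration) composes
the full koff(V) curve used by :mod:`poreblock.blockrelease`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .blockrelease import ReleaseData, pool_geometric
from .simchan import (
    AcquisitionSettings,
    GatingScheme,
    Trace,
    simulate_recording,
)

__all__ = [
    "AmplitudeHistogram",
    "GatingFit",
    "amplitude_histogram",
    "default_bin_edges",
    "predicted_histogram",
    "fit_histogram",
    "blocking_rate_init",
    "open_peak_window",
    "extract_koff",
    "apparent_current",
]

#: fit parameters that are searched in log space (strictly positive rates)
_LOG_PARAMS = {"kOB", "kBO", "kOF", "kFO", "kOM", "kMO", "kOS", "kSO"}
_LINEAR_PARAMS = {"i_true_pA"}


@dataclass(frozen=True)
class AmplitudeHistogram:
    """Per-sample current histogram with explicit under/overflow counts."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    underflow: int = 0
    overflow: int = 0
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing, length >= 2")
        if counts.size != edges.size - 1:
            raise ValueError("counts do not match bin edges")
        if counts.sum() + self.underflow + self.overflow != self.n_total:
            raise ValueError("histogram counts do not conserve the sample count")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def mean(self) -> float:
        """Histogram mean (in-range samples only)."""
        n = self.counts.sum()
        if n == 0:
            return math.nan
        return float((self.bin_centers * self.counts).sum() / n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_pA": self.bin_edges[:-1],
                "bin_right_pA": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def default_bin_edges(
    trace_or_settings: Union[Trace, AcquisitionSettings],
    i_true_pA: Optional[float] = None,
    width_factor: float = 0.5,
) -> np.ndarray:
    """Default binning: width = baseline-noise SD / 2, covering the closed
    peak and the open peak plus three noise SDs on either side."""
    if isinstance(trace_or_settings, Trace):
        sd = trace_or_settings.metadata.get("noise_sd_pA", 0.0) or float(
            np.std(trace_or_settings.current_pA)
        )
        if i_true_pA is None:
            i_true_pA = trace_or_settings.metadata.get("i_true_pA")
        lo_data = float(trace_or_settings.current_pA.min())
        hi_data = float(trace_or_settings.current_pA.max())
    else:
        sd = trace_or_settings.noise_sd_pA
        lo_data, hi_data = 0.0, 0.0
    if i_true_pA is None:
        i_true_pA = hi_data
    sd = max(sd, 1e-6)
    lo = min(0.0, i_true_pA, lo_data) - 3.0 * sd
    hi = max(0.0, i_true_pA, hi_data) + 3.0 * sd
    width = width_factor * sd
    n_bins = max(int(math.ceil((hi - lo) / width)), 10)
    return lo + width * np.arange(n_bins + 1)


def amplitude_histogram(
    trace: Trace,
    bins: Union[int, Sequence[float], None] = None,
) -> AmplitudeHistogram:
    """Histogram of the sampled current (half-open bins, final bin closed).

    Samples outside the range are counted as under/overflow and reported
    rather than dropped silently.
    """
    x = np.asarray(trace.current_pA, dtype=float)
    if x.size == 0:
        raise ValueError("trace is empty")
    if bins is None:
        edges = default_bin_edges(trace)
    elif np.isscalar(bins):
        edges = np.linspace(x.min(), x.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, _ = np.histogram(x, bins=edges)
    underflow = int(np.count_nonzero(x < edges[0]))
    overflow = int(np.count_nonzero(x > edges[-1]))
    return AmplitudeHistogram(
        bin_edges=edges,
        counts=counts,
        n_total=x.size,
        underflow=underflow,
        overflow=overflow,
        metadata=dict(trace.metadata),
    )


def predicted_histogram(
    scheme: GatingScheme,
    settings: AcquisitionSettings,
    n_samples: int,
    seed: Union[int, np.random.SeedSequence],
    bins: Union[Sequence[float], None] = None,
) -> AmplitudeHistogram:
    """Histogram predicted for a parameter set by matched simulation.

    A time series of ``n_samples`` is simulated through the same filter and
    noise chain as the measurement and binned; deterministic given the seed.
    """
    if bins is not None and n_samples < 10 * (len(np.atleast_1d(bins)) - 1):
        import warnings

        warnings.warn(
            f"{n_samples} samples is small for {len(np.atleast_1d(bins)) - 1} bins",
            stacklevel=2,
        )
    duration = n_samples / settings.fs_Hz
    from dataclasses import replace as _replace

    sim_settings = _replace(settings, duration_s=duration)
    trace = simulate_recording(scheme, sim_settings, seed=seed)
    return amplitude_histogram(trace, bins=bins)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingFit:
    """Result of a simplex histogram fit."""

    params: Dict[str, float]
    fixed: Dict[str, float]
    objective: float
    n_eval: int
    converged: bool
    restarts: Tuple[float, ...]
    seed: int
    scheme: GatingScheme
    metadata: Dict = field(default_factory=dict)

    @property
    def kBO(self) -> float:
        return self.params.get("kBO", self.scheme.kBO)

    @property
    def kOB(self) -> float:
        return self.params.get("kOB", self.scheme.kOB)

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "fixed": self.fixed,
            "objective": self.objective,
            "n_eval": self.n_eval,
            "converged": self.converged,
            "restarts": list(self.restarts),
            "seed": self.seed,
            "metadata": {
                k: v for k, v in self.metadata.items() if not isinstance(v, np.ndarray)
            },
        }


def _pooling_map(counts: np.ndarray, min_count: int = 5) -> np.ndarray:
    """Group index per bin such that every group has >= min_count measured
    counts (trailing remainder merged into the last group)."""
    group = np.zeros(counts.size, dtype=np.int64)
    g, acc = 0, 0
    for i, c in enumerate(counts):
        group[i] = g
        acc += int(c)
        if acc >= min_count:
            g += 1
            acc = 0
    if acc > 0 and g > 0:
        group[group == g] = g - 1
    return group


def _pool(values: np.ndarray, group: np.ndarray) -> np.ndarray:
    return np.bincount(group, weights=values)


def _chi2_distance(
    measured: np.ndarray, predicted: np.ndarray, group: np.ndarray
) -> float:
    """Pearson chi-squared between pooled histograms, predicted scaled to the
    measured total."""
    obs = _pool(measured.astype(float), group)
    exp = _pool(predicted.astype(float), group)
    exp = exp * (obs.sum() / max(exp.sum(), 1.0))
    exp = np.maximum(exp, 0.25)  # guard against empty predicted bins
    return float(((obs - exp) ** 2 / exp).sum())


def _apply_params(scheme: GatingScheme, params: Mapping[str, float]) -> GatingScheme:
    return scheme.with_rates(**{("kOB" if k == "kOB" else k): v for k, v in params.items()})


def fit_histogram(
    measured: AmplitudeHistogram,
    template: GatingScheme,
    settings: AcquisitionSettings,
    free: Union[Sequence[str], Mapping[str, float]],
    seed: int = 0,
    restarts: int = 3,
    maxfev: int = 200,
    n_samples: Optional[int] = None,
    perturbation: float = 0.3,
    xatol: float = 0.01,
    fatol: float = 1.0,
    crn_seed: Optional[int] = None,
    window_pA: Optional[Tuple[float, float]] = None,
) -> GatingFit:
    """Nelder-Mead fit of hidden rate constants (and I_true) to a histogram.

    ``free`` names the free parameters ("kOB", "kBO", intrinsic gating rates,
    "i_true_pA"), optionally mapping them to initial values (otherwise the
    template's values are used).  Rates are searched in log space, I_true
    linearly.  Every objective evaluation simulates a matched recording with
    the same common random numbers, so the objective is deterministic; the
    search restarts from perturbed initial points and keeps the best optimum.
    Non-convergence is flagged on the result, not raised.  ``crn_seed``
    overrides the derived common-random-number seed (e.g. to check
    self-consistency against a histogram produced with a known stream).

    ``window_pA`` restricts the compared bins to a current range, typically
    the open-peak neighbourhood (see :func:`open_peak_window`): when the
    intrinsic closed states are held fixed, the mass of the closed peak only
    adds realization noise between the measured and the simulated record, so
    excluding it sharpens the blocking-rate information.
    """
    free_names = list(free)
    if not free_names:
        raise ValueError("at least one free parameter is required")
    for k in free_names:
        if k not in _LOG_PARAMS and k not in _LINEAR_PARAMS:
            raise ValueError(f"unknown fit parameter {k!r}")
    if isinstance(free, Mapping):
        init = {k: float(v) for k, v in free.items()}
    else:
        init = {k: float(getattr(template, k)) for k in free_names}
    for k in free_names:
        if k in _LOG_PARAMS and init[k] <= 0:
            raise ValueError(f"initial value for {k} must be positive")

    if n_samples is None:
        n_samples = measured.n_total
    edges = measured.bin_edges
    if window_pA is not None:
        lo, hi = sorted(window_pA)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mask = (centers >= lo) & (centers <= hi)
        if not mask.any():
            raise ValueError("fit window excludes every histogram bin")
    else:
        mask = np.ones(measured.counts.size, dtype=bool)
    group = _pooling_map(measured.counts[mask])
    # a fixed integer seed (not a SeedSequence, whose spawn counter would
    # advance between evaluations) keeps the common random numbers identical
    # for every objective evaluation of this fit
    if crn_seed is None:
        crn_seed = int(
            np.random.SeedSequence([seed, 0x5EED]).generate_state(1)[0] % (2**31 - 1)
        )

    def pack(values: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [math.log(values[k]) if k in _LOG_PARAMS else values[k] for k in free_names]
        )

    def unpack(x: np.ndarray) -> Dict[str, float]:
        return {
            k: (math.exp(xi) if k in _LOG_PARAMS else xi)
            for k, xi in zip(free_names, x)
        }

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = unpack(x)
        scheme = _apply_params(template, params)
        pred = predicted_histogram(scheme, settings, n_samples, crn_seed, bins=edges)
        return _chi2_distance(measured.counts[mask], pred.counts[mask], group)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    best = None
    restart_objectives: List[float] = []
    x0 = pack(init)
    starts = [x0]
    for _ in range(max(restarts, 0)):
        jitter = rng.normal(0.0, perturbation, x0.size)
        # linear parameters are perturbed relatively, log parameters additively
        xs = x0.copy()
        for j, k in enumerate(free_names):
            if k in _LOG_PARAMS:
                xs[j] = x0[j] + jitter[j]
            else:
                xs[j] = x0[j] * (1.0 + 0.1 * jitter[j])
        starts.append(xs)
    for xs in starts:
        res = optimize.minimize(
            objective,
            xs,
            method="Nelder-Mead",
            options={
                "maxfev": maxfev,
                "xatol": xatol,
                "fatol": fatol,
                "adaptive": True,
            },
        )
        restart_objectives.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res

    params = unpack(best.x)
    fixed = {
        k: getattr(template, k)
        for k in ("kOF", "kFO", "kOM", "kMO", "kOS", "kSO", "i_true_pA")
        if k not in params
    }
    fixed["tpra_mM"] = template.tpra_mM
    if "kOB" not in params:
        fixed["kOB"] = template.kOB
    if "kBO" not in params:
        fixed["kBO"] = template.kBO
    return GatingFit(
        params=params,
        fixed=fixed,
        objective=float(best.fun),
        n_eval=n_eval,
        converged=bool(best.success),
        restarts=tuple(restart_objectives),
        seed=seed,
        scheme=_apply_params(template, params),
        metadata=dict(measured.metadata),
    )


def open_peak_window(i_true_pA: float, noise_sd_pA: float) -> Tuple[float, float]:
    """Current window bracketing the (possibly attenuated) open peak.

    Spans from 40 % of I_true — below any plausible apparent current of a
    partially blocked open channel — to I_true plus four noise SDs, keeping
    the intrinsic closed peak at 0 pA out of the fit.
    """
    lo = 0.4 * i_true_pA
    hi = i_true_pA + 4.0 * noise_sd_pA * (1.0 if i_true_pA >= 0 else -1.0)
    return (lo, hi) if lo <= hi else (hi, lo)


def blocking_rate_init(
    measured: AmplitudeHistogram,
    template: GatingScheme,
    k_total_guess: float = 2.5e5,
) -> Dict[str, float]:
    """Moment-based starting values for a (kOB, kBO) histogram fit.

    For blocking much faster than the filter, the apparent current satisfies
    I_app ~= I_true * P(O | not intrinsically closed) * kBO/(kBO + kOB), which
    pins the ratio of the two rates; the overall speed is started at the
    centre of the detectable range (``k_total_guess``).  Intrinsic gating is
    accounted for through the template's blocker-free open probability.
    """
    from poreblock.ionflux import steady_state

    no_block = template.with_rates(kOB=0.0)
    p_open = float(steady_state(no_block.rate_matrix())[0])
    i_expected = template.i_true_pA * p_open
    if i_expected == 0:
        raise ValueError("template I_true must be non-zero")
    r = measured.mean() / i_expected
    r = float(np.clip(r, 0.02, 0.98))
    return {"kBO": r * k_total_guess, "kOB": (1.0 - r) * k_total_guess}


# ---------------------------------------------------------------------------
# koff assembly and apparent current
# ---------------------------------------------------------------------------

def extract_koff(
    fits: Iterable[GatingFit],
    merge_concentrations: bool = True,
) -> Tuple[ReleaseData, Dict]:
    """Pool fitted kBO values into a per-voltage koff(V) dataset.

    Each fit must carry ``voltage_mV`` and ``tpra_mM`` in its metadata.  The
    per-voltage pooling uses geometric statistics; fits from different
    blocker concentrations are merged (release is concentration independent).
    Diagnostics report the spread of kBO across concentration groups at
    shared voltages and the collapse of kOB / [TPrA] onto konO.
    """
    rows = []
    for fit in fits:
        meta = fit.metadata
        if "voltage_mV" not in meta:
            raise ValueError("fit metadata lacks voltage_mV")
        conc = meta.get("tpra_mM", fit.fixed.get("tpra_mM", math.nan))
        rows.append(
            {
                "voltage_mV": float(meta["voltage_mV"]),
                "koff_per_s": float(fit.kBO),
                "tpra_mM": float(conc) if conc is not None else math.nan,
                "kOB_per_s": float(fit.kOB),
            }
        )
    df = pd.DataFrame(rows)
    pooled = pool_geometric(
        df[["voltage_mV", "koff_per_s", "tpra_mM"]],
        merge_concentrations=merge_concentrations,
    )

    diagnostics: Dict = {"voltages_with_multiple_concentrations": {}, "gap_warning": None}
    multi = df.groupby("voltage_mV")["tpra_mM"].nunique()
    shared = multi[multi > 1].index
    for v in shared:
        vals = df.loc[df["voltage_mV"] == v, "koff_per_s"].to_numpy()
        cv = float(np.std(np.log(vals), ddof=0))
        diagnostics["voltages_with_multiple_concentrations"][float(v)] = {
            "n": int(vals.size),
            "log_spread": cv,
        }
    if merge_concentrations and len(shared) == 0 and df["tpra_mM"].nunique() > 1:
        diagnostics["gap_warning"] = (
            "no voltage is shared between concentration groups; merged curve "
            "has no overlap consistency check"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        kon = df["kOB_per_s"] / (df["tpra_mM"] * 1e-3)
    diagnostics["konO_per_M_s"] = kon.replace([np.inf, -np.inf], np.nan).dropna().to_dict()
    return pooled, diagnostics


def apparent_current(
    trace: Trace,
    i_true_pA: Optional[float] = None,
    settle_s: Optional[float] = None,
) -> Dict[str, float]:
    """Time-averaged (apparent) current of a trace.

    Fast unresolved gating/blocking attenuates the open-channel current, so
    I_app < I_true.  The first two filter time constants are discarded by
    default to avoid the settling transient.  When I_true is supplied (e.g.
    from a fit) the attenuation ratio I_app / I_true is reported as well.
    """
    if trace.n_samples == 0:
        raise ValueError("trace is empty")
    if settle_s is None:
        fc = trace.metadata.get("fc_Hz", 0.0)
        settle_s = 2.0 / (2.0 * math.pi * fc) if fc else 0.0
    start = min(int(settle_s * trace.fs_Hz), trace.n_samples - 1)
    i_app = float(np.mean(trace.current_pA[start:]))
    out = {"i_app_pA": i_app}
    if i_true_pA is None:
        i_true_pA = trace.metadata.get("i_true_pA")
    if i_true_pA:
        out["i_true_pA"] = float(i_true_pA)
        out["ratio"] = i_app / float(i_true_pA)
    return out
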