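"""Steady-state ion occupancy of the K+ channel selectivity filter.

Ion permeation through the selectivity filter (SF) is described as a cyclic
continuous-time Markov chain over a small number of filter configurations
("soft knock-on": K+ ions alternating with water hop between binding-site
arrangements).  Each transition i -> j carries a zero-voltage rate constant
``k0``, a signed electrical distance ``delta`` and optionally a linear
coupling to the K+ activity on one membrane side.  The full rate is the
single-barrier Eyring form

    k_ij(V) = k0_ij * a_coupled * exp(delta_ij * F * V / (R * T))

with the membrane potential ``V`` applied to the cytosolic (cis) side and the
external (trans) side grounded.  The sum of (delta_fwd - delta_rev) around the
cycle equals the total charge translocated per cycle (default one elementary
charge), so the cycle affinity at voltage V is exactly F*V/(R*T) for a
parameter set that satisfies detailed balance at 0 mV.

The occupancy of a binding site (e.g. S4, the site adjacent to a bound pore
blocker) is the summed stationary probability of all states whose annotation
contains that site.  A bound quaternary-ammonium blocker occludes the cavity,
which removes the transitions that exchange the cavity ion with the cytosol:
``apply_block`` zeroes k(1->2), k(2->1) and k(3->2), opening the cycle.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "ELEMENTARY_CHARGE",
    "CYTOSOLIC",
    "EXTERNAL",
    "State",
    "Transition",
    "KineticScheme",
    "BathConditions",
    "OccupancyProfile",
    "FluxResult",
    "SchemeValidationError",
    "MissingActivityError",
    "AmbiguousStationaryError",
    "build_rate_matrix",
    "steady_state",
    "apply_block",
    "site_occupancy",
    "occupancy_vs_voltage",
    "stationary_flux",
    "detailed_balance_residual",
    "kcv_like_scheme",
    "symmetric_kcl_conditions",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
ELEMENTARY_CHARGE = 1.602176634e-19  # C

CYTOSOLIC = "cytosolic"
EXTERNAL = "external"

#: mean activity coefficient used to convert KCl concentration to K+ activity
#: (100 mM KCl -> 77 mM activity)
KCL_ACTIVITY_COEFF = 0.77

BLOCKED_TRANSITIONS = (("1", "2"), ("2", "1"), ("3", "2"))


class SchemeValidationError(ValueError):
    """A kinetic scheme violates a structural invariant."""


class MissingActivityError(KeyError):
    """A concentration-coupled transition has no matching bath activity."""


class AmbiguousStationaryError(RuntimeError):
    """The chain has more than one closed communicating class."""

    def __init__(self, classes):
        self.classes = classes
        super().__init__(
            "stationary distribution is not unique; closed communicating "
            f"classes: {classes}"
        )


@dataclass(frozen=True)
class State:
    """A filter configuration with the set of occupied ion-binding sites."""

    label: str
    sites: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "sites", frozenset(self.sites))


@dataclass(frozen=True)
class Transition:
    """One directed transition of the hopping cycle.

    ``k0`` is the rate at 0 mV and unit activity (s^-1, or s^-1 M^-1 for a
    concentration-coupled transition); ``delta`` the signed electrical
    distance; ``coupling`` an optional (species, side) pair whose bath
    activity multiplies the rate.
    """

    source: str
    target: str
    k0: float
    delta: float = 0.0
    coupling: Optional[Tuple[str, str]] = None

    def __post_init__(self):
        if self.k0 < 0:
            raise SchemeValidationError(
                f"negative rate constant on {self.source}->{self.target}: {self.k0}"
            )
        if self.coupling is not None:
            object.__setattr__(self, "coupling", tuple(self.coupling))


@dataclass(frozen=True)
class KineticScheme:
    """States plus transitions of an ion-hopping model.

    The state order defines the permeation cycle (state i is cycle-adjacent
    to state i+1, and the last state to the first). ``cycle_charge`` is the
    net charge, in elementary charges, translocated per completed forward
    cycle; it scales flux into electrical current.
    """

    states: Tuple[State, ...]
    transitions: Tuple[Transition, ...]
    cycle_charge: float = 1.0
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "transitions", tuple(self.transitions))
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise SchemeValidationError(f"duplicate state labels: {labels}")
        known = set(labels)
        for tr in self.transitions:
            if tr.source not in known or tr.target not in known:
                raise SchemeValidationError(
                    f"transition {tr.source}->{tr.target} references unknown state"
                )
            if tr.source == tr.target:
                raise SchemeValidationError(f"self-transition on {tr.source}")

    # -- convenience accessors -------------------------------------------------
    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(s.label for s in self.states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def sites(self) -> frozenset:
        out = frozenset()
        for s in self.states:
            out = out | s.sites
        return out

    def transition(self, source: str, target: str) -> Transition:
        for tr in self.transitions:
            if tr.source == source and tr.target == target:
                return tr
        raise SchemeValidationError(f"no transition {source}->{target} in scheme")

    def has_transition(self, source: str, target: str) -> bool:
        return any(
            tr.source == source and tr.target == target for tr in self.transitions
        )


@dataclass(frozen=True)
class BathConditions:
    """Voltage, bath activities and temperature.

    ``voltage_mV`` is referenced to the cytosolic (cis) side with the external
    (trans) side grounded; positive values drive outward K+ flux.  Activities
    are in mol/L, keyed by (species, side).
    """

    voltage_mV: float = 0.0
    activities: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    temperature_K: float = 298.15

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        acts = dict(self.activities)
        for key, a in acts.items():
            if a <= 0:
                raise ValueError(f"activity for {key} must be positive, got {a}")
        object.__setattr__(self, "activities", acts)

    @property
    def thermal_voltage_mV(self) -> float:
        """R*T/F in mV (≈25.69 mV at 298.15 K)."""
        return 1000.0 * GAS_CONSTANT * self.temperature_K / FARADAY

    @property
    def reduced_voltage(self) -> float:
        """Dimensionless F*V/(R*T)."""
        return self.voltage_mV / self.thermal_voltage_mV

    def at(self, voltage_mV: float) -> "BathConditions":
        return replace(self, voltage_mV=voltage_mV)


def symmetric_kcl_conditions(
    voltage_mV: float = 0.0,
    kcl_mM: float = 100.0,
    external_kcl_mM: Optional[float] = None,
    temperature_K: float = 298.15,
    activity_coeff: float = KCL_ACTIVITY_COEFF,
) -> BathConditions:
    """Bath conditions for (possibly asymmetric) KCl solutions.

    Activities are ``activity_coeff`` times the concentration, matching the
    77 mM activity of a 100 mM KCl solution.
    """
    ext = kcl_mM if external_kcl_mM is None else external_kcl_mM
    return BathConditions(
        voltage_mV=voltage_mV,
        activities={
            ("K", CYTOSOLIC): activity_coeff * kcl_mM * 1e-3,
            ("K", EXTERNAL): activity_coeff * ext * 1e-3,
        },
        temperature_K=temperature_K,
    )


# ---------------------------------------------------------------------------
# rate matrix and stationary solve
# ---------------------------------------------------------------------------

def build_rate_matrix(scheme: KineticScheme, cond: BathConditions) -> np.ndarray:
    """Generator matrix Q (s^-1) of the scheme under the given conditions.

    Off-diagonal Q[i, j] = k_ij(V); diagonal entries make rows sum to zero.
    """
    n = scheme.n_states
    idx = {lab: i for i, lab in enumerate(scheme.labels)}
    u = cond.reduced_voltage
    Q = np.zeros((n, n))
    for tr in scheme.transitions:
        rate = tr.k0
        if tr.coupling is not None:
            try:
                rate *= cond.activities[tr.coupling]
            except KeyError:
                raise MissingActivityError(
                    f"no activity for {tr.coupling} required by "
                    f"{tr.source}->{tr.target}"
                ) from None
        rate *= math.exp(tr.delta * u)
        Q[idx[tr.source], idx[tr.target]] += rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _closed_classes(Q: np.ndarray) -> list:
    """Closed (recurrent) communicating classes of the jump chain."""
    adj = csr_matrix((Q > 0).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        outside = np.setdiff1d(np.arange(Q.shape[0]), members)
        if outside.size == 0 or not np.any(Q[np.ix_(members, outside)] > 0):
            closed.append(members.tolist())
    return closed


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Unique stationary distribution of a generator matrix.

    Raises :class:`AmbiguousStationaryError` when the chain has several closed
    communicating classes (the stationary vector then depends on the start).
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    if Q.shape != (n, n):
        raise ValueError("Q must be square")
    scale = np.abs(Q).max()
    if scale == 0:
        raise ValueError("Q is identically zero")
    if np.abs(Q.sum(axis=1)).max() > 1e-8 * scale:
        raise ValueError("Q rows must sum to zero (not a generator matrix)")
    closed = _closed_classes(Q)
    if len(closed) != 1:
        raise AmbiguousStationaryError(closed)
    # solve P Q = 0, sum(P) = 1 as an overdetermined least-squares system
    A = np.vstack([Q.T / scale, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    P, *_ = np.linalg.lstsq(A, b, rcond=None)
    P = np.clip(P, 0.0, None)
    P /= P.sum()
    resid = np.abs(P @ Q).max() / scale
    if resid > 1e-9:
        raise RuntimeError(f"stationary solve failed, relative residual {resid:.2e}")
    return P


def apply_block(
    scheme: KineticScheme,
    blocked: Sequence[Tuple[str, str]] = BLOCKED_TRANSITIONS,
) -> KineticScheme:
    """Scheme with the cavity-exchange transitions switched off by a blocker.

    By default k(1->2), k(2->1) and k(3->2) are set to zero: with a blocker in
    the cavity the ion below the filter can neither bind from nor unbind to
    the cytosol, and the S4 ion cannot drop into the cavity. All other rate
    constants are unchanged. The input scheme is not modified.
    """
    for src, tgt in blocked:
        if not scheme.has_transition(src, tgt):
            raise SchemeValidationError(
                f"cannot block missing transition {src}->{tgt}"
            )
    blocked_set = {tuple(p) for p in blocked}
    new_transitions = tuple(
        replace(tr, k0=0.0) if (tr.source, tr.target) in blocked_set else tr
        for tr in scheme.transitions
    )
    name = scheme.name + "+blocked" if scheme.name and not scheme.name.endswith("+blocked") else scheme.name
    return replace(scheme, transitions=new_transitions, name=name)


def site_occupancy(P: np.ndarray, scheme: KineticScheme, site: str) -> float:
    """Probability that the given binding site is occupied: sum of P_m over
    states annotated with the site (e.g. P(S4) = P3 + P4 + P5)."""
    P = np.asarray(P, dtype=float)
    if P.shape[-1] != scheme.n_states:
        raise ValueError("probability vector length does not match scheme")
    if site not in scheme.sites():
        raise SchemeValidationError(f"unknown site label {site!r}")
    mask = np.array([site in s.sites for s in scheme.states])
    return float(P[..., mask].sum(axis=-1)) if P.ndim == 1 else P[..., mask].sum(axis=-1)


@dataclass(frozen=True)
class OccupancyProfile:
    """Stationary state probabilities on a voltage grid plus derived site
    occupancies."""

    voltages_mV: np.ndarray
    P: np.ndarray  # (n_voltages, n_states)
    scheme: KineticScheme
    conditions: BathConditions
    blocked: bool

    def site(self, site: str) -> np.ndarray:
        if site not in self.scheme.sites():
            raise SchemeValidationError(f"unknown site label {site!r}")
        mask = np.array([site in s.sites for s in self.scheme.states])
        return self.P[:, mask].sum(axis=1)

    def state(self, label: str) -> np.ndarray:
        return self.P[:, self.scheme.index(label)]

    def site_interpolator(self, site: str) -> Callable[[np.ndarray], np.ndarray]:
        vals = self.site(site)
        v = self.voltages_mV
        return lambda x: np.interp(np.asarray(x, dtype=float), v, vals)

    def to_frame(self, include_flux: bool = True):
        import pandas as pd

        data = {"voltage_mV": self.voltages_mV}
        for i, lab in enumerate(self.scheme.labels):
            data[f"P{lab}"] = self.P[:, i]
        for site in sorted(self.scheme.sites()):
            data[f"P_{site}"] = self.site(site)
        if include_flux:
            flux = np.empty_like(self.voltages_mV, dtype=float)
            curr = np.empty_like(flux)
            for k, v in enumerate(self.voltages_mV):
                res = stationary_flux(self.scheme, self.conditions.at(v))
                flux[k], curr[k] = res.flux_per_s, res.current_pA
            data["flux_per_s"] = flux
            data["current_pA"] = curr
        return pd.DataFrame(data)


def occupancy_vs_voltage(
    scheme: KineticScheme,
    cond: BathConditions,
    voltages_mV: Sequence[float],
) -> OccupancyProfile:
    """Steady-state occupancies at every voltage of the grid."""
    voltages = np.atleast_1d(np.asarray(voltages_mV, dtype=float))
    if not np.all(np.isfinite(voltages)):
        raise ValueError("voltage grid must be finite")
    P = np.empty((voltages.size, scheme.n_states))
    for k, v in enumerate(voltages):
        P[k] = steady_state(build_rate_matrix(scheme, cond.at(v)))
    return OccupancyProfile(
        voltages_mV=voltages,
        P=P,
        scheme=scheme,
        conditions=cond,
        blocked=not _cycle_closed(scheme),
    )


# ---------------------------------------------------------------------------
# flux and thermodynamic consistency
# ---------------------------------------------------------------------------

def _cycle_edges(scheme: KineticScheme):
    labs = scheme.labels
    n = len(labs)
    return [(labs[i], labs[(i + 1) % n]) for i in range(n)]


def _cycle_closed(scheme: KineticScheme) -> bool:
    for src, tgt in _cycle_edges(scheme):
        for a, b in ((src, tgt), (tgt, src)):
            if not scheme.has_transition(a, b) or scheme.transition(a, b).k0 == 0:
                return False
    return True


@dataclass(frozen=True)
class FluxResult:
    """Net stationary cycle flux (ions/s, positive = forward around the state
    order, i.e. outward for the reference scheme) and the electrical current."""

    flux_per_s: float
    current_pA: float
    open_cycle: bool = False


def stationary_flux(scheme: KineticScheme, cond: BathConditions) -> FluxResult:
    """Net stationary flux around the permeation cycle and current in pA.

    A blocked (open-cycle) scheme carries no net flux; the result is flagged.
    """
    if not _cycle_closed(scheme):
        return FluxResult(0.0, 0.0, open_cycle=True)
    Q = build_rate_matrix(scheme, cond)
    P = steady_state(Q)
    idx = {lab: i for i, lab in enumerate(scheme.labels)}
    J = []
    term_scale = 0.0
    for src, tgt in _cycle_edges(scheme):
        i, j = idx[src], idx[tgt]
        fwd = P[i] * Q[i, j]
        rev = P[j] * Q[j, i]
        term_scale = max(term_scale, fwd, rev)
        J.append(fwd - rev)
    J = np.array(J)
    spread = J.max() - J.min()
    tol = 1e-8 * max(abs(J).max(), term_scale * 1e-4)
    if spread > max(tol, 1e-300):
        raise RuntimeError(
            f"edge fluxes inconsistent (spread {spread:.3e} for flux {J.mean():.3e})"
        )
    flux = float(J.mean())
    current_pA = scheme.cycle_charge * ELEMENTARY_CHARGE * flux * 1e12
    return FluxResult(flux, current_pA, open_cycle=False)


def detailed_balance_residual(scheme: KineticScheme, cond: BathConditions) -> float:
    """Cycle affinity ln(prod forward / prod backward), dimensionless.

    Zero signals thermodynamic consistency (micro-reversibility); a zero rate
    anywhere on the cycle gives an infinite affinity (open cycle).
    """
    Q = build_rate_matrix(scheme, cond)
    idx = {lab: i for i, lab in enumerate(scheme.labels)}
    log_fwd = 0.0
    log_rev = 0.0
    fwd_zero = rev_zero = False
    for src, tgt in _cycle_edges(scheme):
        i, j = idx[src], idx[tgt]
        if Q[i, j] <= 0:
            fwd_zero = True
        else:
            log_fwd += math.log(Q[i, j])
        if Q[j, i] <= 0:
            rev_zero = True
        else:
            log_rev += math.log(Q[j, i])
    if fwd_zero and rev_zero:
        return math.inf  # fully interrupted cycle: open-cycle condition
    if fwd_zero:
        return -math.inf
    if rev_zero:
        return math.inf
    return log_fwd - log_rev


# ---------------------------------------------------------------------------
# reference scheme
# ---------------------------------------------------------------------------

def kcv_like_scheme() -> KineticScheme:
    """Synthetic default parameter set for the 5-state hopping cycle.

    This is a documented stand-in with kcv-like magnitudes (hopping rates of
    order 1e8 s^-1, single-channel currents of a few pA), not a fitted set:
    states 1 and 2 have S2/S4 empty, states 3-5 carry ions in S2 and S4, entry
    from the cytosol (1->2) scales with cytosolic K+ activity and entry from
    the external side (5->4) with external activity.  k23 is computed from the
    detailed-balance constraint so the cycle is exactly micro-reversible at
    0 mV in symmetric solutions, and the electrical distances sum to one
    elementary charge per cycle.  P(S4) of the blocked scheme rises
    monotonically from ≈0.34 at −160 mV to ≈0.97 at +160 mV.
    """
    s = 4.0  # overall rate scale (sets the current magnitude, not occupancies)
    k12, k21 = s * 8.0e8, s * 2.0e8  # cytosolic entry/exit (k12 per M)
    k32 = s * 5.0e7
    k34, k43 = s * 1.0e8, s * 6.0e7
    k45 = s * 4.0e7
    k54 = s * 4.0e7 / 0.077          # external entry (per M)
    k51, k15 = s * 5.0e7, s * 6.0e7
    # detailed balance at 0 mV, symmetric activities:
    # k12 k23 k34 k45 k51 = k21 k32 k43 k54 k15
    k23 = (k21 * k32 * k43 * k54 * k15) / (k12 * k34 * k45 * k51)

    # per-edge translocated charge q = delta_fwd - delta_rev, sum over cycle = 1
    d12, d23, d34, d45, d51 = 0.425, 0.325, -0.075, -0.075, -0.100

    sites = frozenset({"S2", "S4"})
    states = (
        State("1"), State("2"),
        State("3", sites), State("4", sites), State("5", sites),
    )
    transitions = (
        Transition("1", "2", k12, d12, ("K", CYTOSOLIC)),
        Transition("2", "1", k21, -d12),
        Transition("2", "3", k23, d23),
        Transition("3", "2", k32, -d23),
        Transition("3", "4", k34, d34),
        Transition("4", "3", k43, -d34),
        Transition("4", "5", k45, d45),
        Transition("5", "4", k54, -d45, ("K", EXTERNAL)),
        Transition("5", "1", k51, d51),
        Transition("1", "5", k15, -d51),
    )
    return KineticScheme(states=states, transitions=transitions,
                         cycle_charge=1.0, name="kcv-like")
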