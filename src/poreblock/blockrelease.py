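"""Two-parameter model of voltage-dependent pore-blocker release.

Release of a cationic blocker from the cavity of a K+ channel is an Eyring
barrier crossing whose barrier height depends on whether the adjacent filter
site S4 holds a K+ ion.  Weighting the two scenarios by the S4 occupation
probability P(S4, V) gives a release rate that is linear in P(S4):

    koff(V) = a * (1 - P(S4,V)) + c * P(S4,V) = a + b * P(S4,V),   b = c - a

``a`` is the release rate with S4 empty, ``c`` with S4 occupied.  The entire
voltage dependence enters through P(S4, V); a and b are voltage independent.
The ion-induced change of the release barrier follows from a and b alone:

    ddG = G_ion - G_0 = -ln(1 + b/a)   (in kT)

Absolute barriers and the attempt prefactor are not identifiable from koff
data and are never reported.  The module also provides the bookkeeping for a
thermodynamic-cycle estimate of the blocker-release free energy from excess
chemical potentials of the channel with/without blocker and S4 ion, and the
z*F*V electrical energy scale used to argue that the direct effect of voltage
on the blocker is negligible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .ionflux import (
    FARADAY,
    GAS_CONSTANT,
    BathConditions,
    KineticScheme,
    apply_block,
    occupancy_vs_voltage,
)

__all__ = [
    "BlockerReleaseModel",
    "ReleaseData",
    "EnergeticsCycle",
    "PredictionCurve",
    "UnidentifiableError",
    "koff_model",
    "fit_release",
    "predict_asymmetric",
    "delta_delta_G",
    "release_energy_cycle",
    "voltage_energy",
    "pool_geometric",
]


class UnidentifiableError(RuntimeError):
    """The (a, b) parameters cannot be resolved from the supplied data."""


@dataclass(frozen=True)
class BlockerReleaseModel:
    """Fitted release-model parameters.

    a : release rate with S4 empty (s^-1)
    b : c - a, the slope against P(S4) (s^-1)
    cov : 2x2 covariance of (a, b) from the fit; zeros when constructed
        directly from known parameters.
    """

    a: float
    b: float
    cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    temperature_K: float = 298.15
    n_obs: int = 0
    dof: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        # a > 0 and c = a + b > 0 hold for the physical model; noisy fits can
        # produce estimates outside that region, which must still be
        # representable (their energetics then raise a domain error).
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("a and b must be finite")

    @property
    def c(self) -> float:
        """Release rate with S4 occupied (s^-1)."""
        return self.a + self.b

    def koff(self, p_s4) -> np.ndarray:
        return koff_model(p_s4, self)

    def ddG_kT(self) -> float:
        return delta_delta_G(self)[0]

    def ddG_kJmol(self) -> float:
        return delta_delta_G(self)[1]

    def standard_errors(self) -> Tuple[float, float]:
        return float(np.sqrt(self.cov[0, 0])), float(np.sqrt(self.cov[1, 1]))

    def _tq(self, level: float) -> float:
        if self.dof <= 0:
            return stats.norm.ppf(0.5 + level / 2)
        return stats.t.ppf(0.5 + level / 2, self.dof)

    def confidence_band(self, p_s4, level: float = 0.99):
        """Delta-method confidence band of the mean koff at given P(S4)."""
        p = np.atleast_1d(np.asarray(p_s4, dtype=float))
        X = np.column_stack([np.ones_like(p), p])
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov, X))
        mid = self.a + self.b * p
        half = self._tq(level) * se
        return mid - half, mid + half

    def parameter_ci(self, level: float = 0.99):
        tq = self._tq(level)
        se_a, se_b = self.standard_errors()
        return (
            (self.a - tq * se_a, self.a + tq * se_a),
            (self.b - tq * se_b, self.b + tq * se_b),
        )

    def to_dict(self) -> dict:
        ddg_kt, ddg_kj = delta_delta_G(self)
        return {
            "a_per_s": self.a,
            "b_per_s": self.b,
            "c_per_s": self.c,
            "cov": self.cov.tolist(),
            "temperature_K": self.temperature_K,
            "n_obs": self.n_obs,
            "dof": self.dof,
            "ddG_kT": ddg_kt,
            "ddG_kJmol": ddg_kj,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlockerReleaseModel":
        return cls(
            a=d["a_per_s"],
            b=d["b_per_s"],
            cov=np.asarray(d.get("cov", np.zeros((2, 2)))),
            temperature_K=d.get("temperature_K", 298.15),
            n_obs=d.get("n_obs", 0),
            dof=d.get("dof", 0),
        )


@dataclass(frozen=True)
class ReleaseData:
    """Per-voltage pooled blocker release rates.

    gsd is the geometric standard deviation (>= 1, dimensionless), n the
    number of channels pooled; tpra_mM is NaN for records merged across
    blocker concentrations.
    """

    voltage_mV: np.ndarray
    koff_per_s: np.ndarray
    gsd: np.ndarray
    n: np.ndarray
    tpra_mM: np.ndarray

    def __post_init__(self):
        for name in ("voltage_mV", "koff_per_s", "gsd", "n", "tpra_mM"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if np.any(self.koff_per_s <= 0):
            raise ValueError("koff values must be positive")
        if np.any(self.gsd < 1):
            raise ValueError("geometric SD must be >= 1")

    def __len__(self) -> int:
        return self.voltage_mV.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voltage_mV": self.voltage_mV,
                "koff_per_s": self.koff_per_s,
                "gsd": self.gsd,
                "n": self.n,
                "tpra_mM": self.tpra_mM,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReleaseData":
        return cls(
            voltage_mV=df["voltage_mV"].to_numpy(),
            koff_per_s=df["koff_per_s"].to_numpy(),
            gsd=df["gsd"].to_numpy() if "gsd" in df else np.ones(len(df)),
            n=df["n"].to_numpy() if "n" in df else np.ones(len(df)),
            tpra_mM=df["tpra_mM"].to_numpy() if "tpra_mM" in df else np.full(len(df), np.nan),
        )


@dataclass(frozen=True)
class EnergeticsCycle:
    """Excess chemical potentials (kJ/mol) entering the release-energy cycle.

    mu_* are the solvation excess chemical potentials of the bare channel, the
    channel with a K+ ion at S4, the channel with blocker, and the channel
    with both; delta_E is the direct blocker-ion interaction energy.
    """

    mu_channel: float
    mu_channel_K: float
    mu_channel_blocker: float
    mu_channel_blocker_K: float
    delta_E: float

    def __post_init__(self):
        for name in ("mu_channel", "mu_channel_K", "mu_channel_blocker",
                     "mu_channel_blocker_K", "delta_E"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v}")


# ---------------------------------------------------------------------------
# model evaluation and fitting
# ---------------------------------------------------------------------------

def koff_model(p_s4, model: BlockerReleaseModel):
    """Release rate a + b * P(S4) for scalar or array P(S4)."""
    p = np.asarray(p_s4, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("P(S4) must lie in [0, 1]")
    out = model.a + model.b * p
    return float(out) if np.isscalar(p_s4) or p.ndim == 0 else out


def fit_release(
    data: ReleaseData,
    p_s4: Union[Sequence[float], Callable],
    weights: Optional[str] = None,
    temperature_K: float = 298.15,
) -> BlockerReleaseModel:
    """Least-squares fit of koff = a + b * P(S4) to pooled release data.

    ``p_s4`` is either an array aligned with ``data`` or a callable mapping
    voltage (mV) to the blocked-channel S4 occupancy.  ``weights=None`` is
    ordinary least squares; ``weights='inverse_square'`` weights residuals by
    1/koff^2 (log-consistent for lognormally dispersed rates);
    ``weights='relative'`` iteratively reweights by 1/fitted^2, which avoids
    the bias of weighting by the noisy observations themselves.
    """
    if len(data) < 3 or np.unique(data.voltage_mV).size < 3:
        raise UnidentifiableError("need koff data at >= 3 distinct voltages")
    p = np.asarray(p_s4(data.voltage_mV) if callable(p_s4) else p_s4, dtype=float)
    if p.shape != data.voltage_mV.shape:
        raise ValueError("P(S4) values do not align with the data")
    if np.ptp(p) < 1e-12:
        raise UnidentifiableError(
            "P(S4) is constant across the data; a and b cannot be separated"
        )
    y = data.koff_per_s
    X = np.column_stack([np.ones_like(p), p])
    if weights is None:
        w = np.ones_like(y)
    elif weights == "inverse_square":
        w = 1.0 / y**2
    elif weights == "relative":
        w = np.ones_like(y)
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    n_reweight = 2 if weights == "relative" else 0
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    for _ in range(n_reweight):
        yhat = np.maximum(X @ beta, 1e-3 * float(np.abs(y).mean()))
        w = 1.0 / yhat**2
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    dof = len(y) - 2
    sigma2 = float(resid @ (w * resid)) / dof if dof > 0 else 0.0
    XtWX_inv = np.linalg.inv(X.T @ (X * w[:, None]))
    cov = sigma2 * XtWX_inv
    return BlockerReleaseModel(
        a=float(beta[0]), b=float(beta[1]), cov=cov,
        temperature_K=temperature_K, n_obs=len(y), dof=dof,
    )


@dataclass(frozen=True)
class PredictionCurve:
    """koff(V) prediction with confidence band."""

    voltage_mV: np.ndarray
    p_s4: np.ndarray
    koff_per_s: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voltage_mV": self.voltage_mV,
                "P_S4": self.p_s4,
                "koff_per_s": self.koff_per_s,
                f"ci{int(self.level*100)}_lower": self.lower,
                f"ci{int(self.level*100)}_upper": self.upper,
            }
        )


def predict_asymmetric(
    model: BlockerReleaseModel,
    scheme: KineticScheme,
    cond: BathConditions,
    voltages_mV: Sequence[float],
    site: str = "S4",
    level: float = 0.99,
    already_blocked: bool = False,
) -> PredictionCurve:
    """Predicted koff(V) under arbitrary (e.g. asymmetric) bath conditions.

    The S4 occupancy is recomputed with the blocked hopping scheme under the
    supplied conditions; a and b are taken unchanged from the fitted model, so
    under the fit's own conditions this reproduces the fitted curve.
    """
    blocked = scheme if already_blocked else apply_block(scheme)
    prof = occupancy_vs_voltage(blocked, cond, voltages_mV)
    p = prof.site(site)
    mid = model.a + model.b * p
    lo, hi = model.confidence_band(p, level=level)
    return PredictionCurve(
        voltage_mV=prof.voltages_mV, p_s4=p, koff_per_s=mid,
        lower=lo, upper=hi, level=level,
    )


# ---------------------------------------------------------------------------
# energetics
# ---------------------------------------------------------------------------

def delta_delta_G(model: BlockerReleaseModel) -> Tuple[float, float]:
    """Ion-induced change of the release barrier, (kT, kJ/mol).

    ddG = -ln(1 + b/a); negative values mean the S4 ion lowers the barrier.
    """
    ratio = 1.0 + model.b / model.a
    if ratio <= 0:
        raise ValueError("1 + b/a must be positive")
    ddg_kt = -math.log(ratio)
    ddg_kj = ddg_kt * GAS_CONSTANT * model.temperature_K / 1000.0
    return ddg_kt, ddg_kj


def release_energy_cycle(cycle: EnergeticsCycle) -> float:
    """Relative blocker-release free energy (kJ/mol) from the thermodynamic
    cycle of excess chemical potentials:

        mu(ch+K) - mu(ch+blocker+K) - [mu(ch) - mu(ch+blocker)] - delta_E
    """
    return (
        cycle.mu_channel_K
        - cycle.mu_channel_blocker_K
        - (cycle.mu_channel - cycle.mu_channel_blocker)
        - cycle.delta_E
    )


def voltage_energy(charge_e: float, voltage_mV: float) -> float:
    """Electrical energy z*F*V in kJ/mol (z in elementary charges, V in mV)."""
    return charge_e * FARADAY * voltage_mV * 1e-3 / 1000.0


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_geometric(
    records: Union[pd.DataFrame, Iterable[Tuple]],
    merge_concentrations: bool = True,
) -> ReleaseData:
    """Pool per-channel koff values into per-voltage geometric statistics.

    ``records`` is a DataFrame (or iterable of tuples) with columns
    voltage_mV, koff_per_s and optionally tpra_mM.  Values are pooled by
    voltage with the geometric mean and geometric SD; groups measured at
    different blocker concentrations are merged at overlapping voltages by
    default, since blocker release does not depend on blocker concentration.
    """
    if not isinstance(records, pd.DataFrame):
        rows = list(records)
        ncol = len(rows[0]) if rows else 2
        cols = ["voltage_mV", "koff_per_s", "tpra_mM"][:ncol]
        records = pd.DataFrame(rows, columns=cols)
    if "tpra_mM" not in records:
        records = records.assign(tpra_mM=np.nan)
    if np.any(records["koff_per_s"].to_numpy() <= 0):
        raise ValueError("koff values must be positive")

    keys = ["voltage_mV"] if merge_concentrations else ["voltage_mV", "tpra_mM"]
    out = []
    for key, grp in records.groupby(keys, dropna=False, sort=True):
        vals = grp["koff_per_s"].to_numpy(dtype=float)
        gmean = float(stats.gmean(vals))
        if vals.size > 1 and np.ptp(np.log(vals)) > 0:
            gsd = float(stats.gstd(vals))
        else:
            gsd = 1.0
        concs = grp["tpra_mM"].dropna().unique()
        conc = float(concs[0]) if concs.size == 1 else np.nan
        v = key[0] if isinstance(key, tuple) else key
        out.append((v, gmean, gsd, vals.size, conc))
    arr = np.array(out, dtype=float)
    return ReleaseData(
        voltage_mV=arr[:, 0], koff_per_s=arr[:, 1], gsd=arr[:, 2],
        n=arr[:, 3], tpra_mM=arr[:, 4],
    )
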