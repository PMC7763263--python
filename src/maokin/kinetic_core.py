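"""Core kinetic scheme for mechanism-based (suicide) inactivation.

The reaction network is

    E + I  <=>[k_on/k_off]  E.I  -->[k_ox]  E.I*
    E.I*  -->[k_rel]  E + P      (product release; E recycles if O2 present)
    E.I*  -->[k_chem] E-I        (covalent adduct, catalytically dead)

Species are tracked in micromolar; time in minutes; first-order rates in
min^-1 and the association rate in uM^-1 min^-1.  In aerobic mode the
enzyme released from E.I* is reoxidized instantly and re-enters the free
oxidized pool; in anaerobic mode it stays reduced and catalytically inert
(pre-reduced MAO neither oxidizes a propargylamine nor forms the adduct).

Derived macroscopic parameters under the rapid-equilibrium assumption
(k_off >> k_ox):

    Ki      = k_off / k_on
    k_inact = k_ox * k_chem / (k_ox + k_rel + k_chem)
    K_I     = Ki * (k_rel + k_chem) / (k_ox + k_rel + k_chem)
    r       = k_rel / k_chem          (partition ratio)
    k_obs   = k_inact * I / (K_I * (1 + S/KM) + I)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ValidationError

#: column order for trajectory state matrices and CSV export
STATE_COLUMNS = (
    "E_ox_free", "EI", "EIstar", "E_adduct", "E_red_free", "I_free", "P_released",
)

#: threshold below which the rapid-equilibrium closed forms degrade
RAPID_EQ_FACTOR = 20.0


@dataclass(frozen=True)
class RateSet:
    """Microscopic rate constants of the inactivation scheme.

    Parameters
    ----------
    k_on : float
        Association rate constant (uM^-1 min^-1), k+1.
    k_off : float
        Dissociation rate constant (min^-1), k-1.
    k_ox : float
        Catalytic oxidation rate constant (min^-1), k+2.
    k_rel : float
        Product release rate constant (min^-1), k+3.
    k_chem : float
        Covalent adduct formation rate constant (min^-1), k+4.
    """

    k_on: float
    k_off: float
    k_ox: float
    k_rel: float
    k_chem: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_ox", "k_rel", "k_chem"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if self.k_on <= 0:
            raise ValidationError("k_on must be > 0")
        if self.k_ox > 0 and self.k_rel == 0 and self.k_chem == 0:
            raise ValidationError(
                "E.I* has no exit: k_ox > 0 requires k_rel > 0 or k_chem > 0"
            )

    @property
    def Ki(self) -> float:
        """Reversible dissociation constant k_off/k_on (uM)."""
        return self.k_off / self.k_on

    @property
    def is_rapid_equilibrium(self) -> bool:
        """True when binding equilibrates much faster than catalysis."""
        return self.k_off >= RAPID_EQ_FACTOR * self.k_ox


@dataclass(frozen=True)
class DerivedParams:
    """Macroscopic parameters derived from a :class:`RateSet`.

    ``r`` is NaN when ``k_chem == 0`` (the compound is a substrate, not an
    inactivator; every turnover releases product).  ``rapid_equilibrium``
    records whether the closed forms are trustworthy for the source rates.
    """

    Ki: float
    r: float
    k_inact: float
    K_I: float
    specificity: float
    rapid_equilibrium: bool = True

    @property
    def is_inactivating(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class SubstrateParams:
    """Michaelis-Menten substrate context: KM and S in uM, kcat in min^-1."""

    KM: float
    kcat: float = 1.0
    S: float = 0.0

    def __post_init__(self) -> None:
        if self.KM <= 0:
            raise ValidationError(f"KM must be > 0, got {self.KM}")
        if self.kcat < 0 or self.S < 0:
            raise ValidationError("kcat and S must be >= 0")

    @property
    def protection_factor(self) -> float:
        """Competitive protection 1 + S/KM against inactivator binding."""
        return 1.0 + self.S / self.KM


@dataclass
class Trajectory:
    """ODE solution: species concentrations (uM) on a time grid (min)."""

    times: np.ndarray
    states: pd.DataFrame
    mode: str
    rates: RateSet
    E_total: float = field(default=0.0)
    I_total: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)

    def active_fraction(self) -> np.ndarray:
        """Recoverable activity: every enzyme form except the covalent
        adduct and the inert reduced pool, as a fraction of total enzyme."""
        if self.E_total == 0:
            return np.ones_like(self.times)
        live = (
            self.states["E_ox_free"] + self.states["EI"] + self.states["EIstar"]
        )
        return (live / self.E_total).to_numpy()

    def conservation_error(self) -> tuple[float, float]:
        """Max relative violation of the enzyme and inactivator balances."""
        s = self.states
        e_sum = s[["E_ox_free", "EI", "EIstar", "E_adduct", "E_red_free"]].sum(axis=1)
        i_sum = s[["I_free", "EI", "EIstar", "P_released", "E_adduct"]].sum(axis=1)
        e_err = 0.0 if self.E_total == 0 else float(
            np.max(np.abs(e_sum - self.E_total)) / self.E_total)
        i_err = 0.0 if self.I_total == 0 else float(
            np.max(np.abs(i_sum - self.I_total)) / self.I_total)
        return e_err, i_err

    def to_frame(self) -> pd.DataFrame:
        out = self.states.copy()
        out.insert(0, "time_min", self.times)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs(t, y, k_on, k_off, k_ox, k_rel, k_chem, aerobic):
    E, EI, EIs, Ead, Ered, I, P = y
    bind = k_on * E * I
    unbind = k_off * EI
    oxidize = k_ox * EI
    release = k_rel * EIs
    adduct = k_chem * EIs
    dE = -bind + unbind + (release if aerobic else 0.0)
    dEI = bind - unbind - oxidize
    dEIs = oxidize - release - adduct
    dEad = adduct
    dEred = 0.0 if aerobic else release
    dI = -bind + unbind
    dP = release
    return [dE, dEI, dEIs, dEad, dEred, dI, dP]


def simulate(
    rates: RateSet,
    E_total: float,
    I_total: float,
    times,
    mode: str = "aerobic",
) -> Trajectory:
    """Integrate the inactivation scheme on a fixed time grid.

    Parameters
    ----------
    rates : RateSet
        Microscopic rate constants.
    E_total, I_total : float
        Total enzyme and inactivator concentrations (uM).
    times : array-like
        Strictly increasing sample times in minutes; t=0 need not be first
        but the integration starts at ``times[0]`` from the fully
        free/oxidized initial condition.
    mode : {"aerobic", "anaerobic"}
        Aerobic: enzyme released from E.I* is instantly reoxidized and
        recycles.  Anaerobic: released enzyme enters an inert reduced pool.

    Returns
    -------
    Trajectory
        States at every requested time; both conservation laws hold to
        the integrator tolerance (~1e-10 relative).
    """
    if mode not in ("aerobic", "anaerobic"):
        raise ValidationError(f"mode must be 'aerobic' or 'anaerobic', got {mode!r}")
    if E_total < 0 or I_total < 0:
        raise ValidationError("E_total and I_total must be >= 0")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be a strictly increasing 1-D grid")
    if times[0] < 0:
        raise ValidationError("times must be nonnegative")

    y0 = np.array([E_total, 0.0, 0.0, 0.0, 0.0, I_total, 0.0])
    return integrate_states(rates, y0, times, mode)


def integrate_states(rates: RateSet, y0, times, mode: str = "aerobic") -> Trajectory:
    """Integrate from an arbitrary state vector (order :data:`STATE_COLUMNS`).

    Used to continue a run after an external perturbation such as adding
    more inactivator mid-titration; conservation totals are recomputed
    from ``y0``.
    """
    if mode not in ("aerobic", "anaerobic"):
        raise ValidationError(f"mode must be 'aerobic' or 'anaerobic', got {mode!r}")
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (7,) or np.any(y0 < 0):
        raise ValidationError("state vector must be 7 nonnegative concentrations")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValidationError("times must be a strictly increasing 1-D grid")
    E_total = float(y0[[0, 1, 2, 3, 4]].sum())
    I_total = float(y0[[5, 1, 2, 6, 3]].sum())
    scale = max(E_total, I_total, 1e-12)
    sol = solve_ivp(
        _rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12 * scale,
        args=(rates.k_on, rates.k_off, rates.k_ox, rates.k_rel, rates.k_chem,
              mode == "aerobic"),
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed ({sol.message}) for rates k_on={rates.k_on}, "
            f"k_off={rates.k_off}, k_ox={rates.k_ox}, k_rel={rates.k_rel}, "
            f"k_chem={rates.k_chem}"
        )
    y = np.clip(sol.y.T, 0.0, None)  # clip integrator noise at -1e-15 level
    states = pd.DataFrame(y, columns=list(STATE_COLUMNS))
    return Trajectory(times=times, states=states, mode=mode, rates=rates,
                      E_total=E_total, I_total=I_total)


def derive_kitz_wilson(rates: RateSet) -> DerivedParams:
    """Closed-form macroscopic parameters under rapid equilibrium.

    Uses k_inact = k_ox*k_chem/(k_ox + k_rel + k_chem) and
    K_I = Ki*(k_rel + k_chem)/(k_ox + k_rel + k_chem).  When
    ``k_off < 20*k_ox`` the rapid-equilibrium assumption is dubious; the
    result carries ``rapid_equilibrium=False`` and a warning is emitted.
    ``k_chem == 0`` yields k_inact = 0 and r = NaN (not inactivating).
    """
    Ki = rates.Ki
    exit_sum = rates.k_rel + rates.k_chem
    if rates.k_chem == 0:
        r = math.nan
        k_inact = 0.0
    else:
        r = rates.k_rel / rates.k_chem
        k_inact = rates.k_ox * rates.k_chem / (rates.k_ox + exit_sum)
    if exit_sum > 0:
        K_I = Ki * exit_sum / (rates.k_ox + exit_sum)
    else:
        K_I = Ki  # k_ox = 0: plain reversible binding
    specificity = k_inact / K_I if K_I > 0 else math.nan
    req = rates.is_rapid_equilibrium
    if not req:
        warnings.warn(
            "k_off < 20*k_ox: rapid-equilibrium closed forms may be inaccurate",
            stacklevel=2,
        )
    return DerivedParams(Ki=Ki, r=r, k_inact=k_inact, K_I=K_I,
                         specificity=specificity, rapid_equilibrium=req)


def k_obs_analytic(
    rates: RateSet,
    I: float,
    substrate: SubstrateParams | None = None,
) -> float:
    """Pseudo-first-order inactivation rate at inhibitor concentration I.

    k_obs = k_inact * I / (K_I * (1 + S/KM) + I); without substrate the
    competitive protection factor is 1.
    """
    if I < 0:
        raise ValidationError(f"I must be >= 0, got {I}")
    dp = derive_kitz_wilson(rates)
    protection = substrate.protection_factor if substrate is not None else 1.0
    denom = dp.K_I * protection + I
    if denom == 0:
        return 0.0
    return dp.k_inact * I / denom
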