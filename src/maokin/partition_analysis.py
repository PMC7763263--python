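"""Partition-ratio titration and active-site titration.

The partition ratio r = k_rel/k_chem counts inactivator molecules
oxidized and released per enzyme molecule covalently inactivated.  In a
long incubation that consumes all the inactivator, each consumed
molecule kills the enzyme with probability 1/(r+1), so the remaining
activity falls linearly with the load ratio x = I0/E0:

    activity% = 100 * max(0, 1 - x/(r+1))

and the x-intercept of the descending linear asymptote is r + 1.  The
same endpoint, run with a low-r inactivator of known partition ratio,
titrates the functional enzyme concentration (active-site titration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RangeError, ValidationError
from .kinetic_core import (
    RateSet,
    derive_kitz_wilson,
    integrate_states,
    k_obs_analytic,
)

#: default descending-region selection window (fractional activity)
WINDOW = (0.10, 0.90)

#: "no further inactivation": activity change per sampling interval below this
COMPLETION_TOL_PCT = 0.1

#: beyond this horizon the analytic complete-consumption endpoint is used
ANALYTIC_CUTOFF_MIN = 1e4


@dataclass
class PartitionTitration:
    """Endpoint activities vs load ratio x = I0/E0."""

    ratio_x: np.ndarray
    activity_pct: np.ndarray
    complete: np.ndarray  # bool per point
    E0: float = float("nan")

    def __post_init__(self) -> None:
        self.ratio_x = np.asarray(self.ratio_x, dtype=float)
        self.activity_pct = np.asarray(self.activity_pct, dtype=float)
        self.complete = np.asarray(self.complete, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ratio_x": self.ratio_x,
            "activity_pct": self.activity_pct,
            "complete_flag": self.complete.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PartitionTitration":
        return cls(df["ratio_x"].to_numpy(), df["activity_pct"].to_numpy(),
                   df["complete_flag"].to_numpy().astype(bool))


@dataclass(frozen=True)
class PartitionEstimate:
    r: float
    r_stderr: float | None
    intercept_x: float
    n_points_used: int
    censored: bool = False  # True when the grid never reached zero activity


def _endpoint_activity_pct(r: float, x: np.ndarray) -> np.ndarray:
    """Complete-consumption endpoint: linear decline hitting zero at r+1."""
    return 100.0 * np.clip(1.0 - x / (r + 1.0), 0.0, None)


def titrate_to_completion(
    rates: RateSet,
    E0: float,
    I0_grid,
    max_time: float = 14400.0,
) -> PartitionTitration:
    """Simulate the long-incubation titration to its endpoint.

    Each inhibitor load is integrated (aerobic, no substrate) until the
    activity change per sampling interval drops below 0.1% — the
    operational "no further inactivation" criterion — or ``max_time``
    (min) is reached, in which case the point is flagged incomplete but
    retained.  For runs whose completion horizon exceeds 1e4 min the
    analytic complete-consumption endpoint is used instead of the stiff
    multi-day integration (the two agree on shorter runs; see tests).
    """
    if E0 <= 0:
        raise ValidationError("E0 must be > 0")
    I0_grid = np.asarray(I0_grid, dtype=float)
    if np.any(I0_grid < 0):
        raise ValidationError("I0 values must be >= 0")
    dp = derive_kitz_wilson(rates)
    if not dp.is_inactivating:
        raise ValidationError("k_chem = 0: the compound never inactivates, "
                              "the titration has no endpoint")

    x = I0_grid / E0
    act = np.empty_like(x)
    complete = np.ones(x.shape, dtype=bool)
    for i, I0 in enumerate(I0_grid):
        if I0 == 0:
            act[i] = 100.0
            continue
        # the run ends when whichever resource runs out first is exhausted:
        # inhibitor consumption at (r+1)*k_inact per surviving site, or
        # enzyme death at k_obs(I0); pad 10x for the asymptotic tail
        surviving = max(1.0 - x[i] / (dp.r + 1.0), 0.1)
        t_consume = 10.0 * (I0 + dp.K_I) / (
            (dp.r + 1.0) * dp.k_inact * E0 * surviving)
        t_kill = 10.0 / max(k_obs_analytic(rates, I0), 1e-300)
        t_est = min(t_consume, t_kill)
        if t_est >= ANALYTIC_CUTOFF_MIN:
            # multi-week horizon: use the complete-consumption endpoint
            act[i] = _endpoint_activity_pct(dp.r, np.array([x[i]]))[0]
            continue
        # chunked continuation: double the window until the activity stops
        # moving (change over a whole chunk below the completion tolerance)
        y = np.array([E0, 0.0, 0.0, 0.0, 0.0, I0, 0.0])
        elapsed, window = 0.0, min(t_est, max_time)
        frac = 100.0
        while True:
            times = np.linspace(0.0, window, 200)
            traj = integrate_states(rates, y, times, mode="aerobic")
            y = traj.states.iloc[-1].to_numpy().clip(0.0)
            prev, frac = frac, traj.active_fraction()[-1] * 100.0
            elapsed += window
            if abs(prev - frac) < COMPLETION_TOL_PCT:
                break
            if elapsed >= max_time:
                complete[i] = False
                break
            window = min(2.0 * window, max_time - elapsed)
        act[i] = frac
    return PartitionTitration(ratio_x=x, activity_pct=act, complete=complete,
                              E0=E0)


def estimate_partition(
    titration: PartitionTitration,
    window: tuple = WINDOW,
) -> PartitionEstimate:
    """Linear-asymptote intercept estimator of the partition ratio.

    An OLS line through the points with fractional activity inside
    ``window`` (default 10-90%) is extrapolated to activity = 0; the
    intercept x0 equals r + 1, so the estimate is x0 - 1.  Raises
    :class:`RangeError` when fewer than 3 points fall in the descending
    region.
    """
    x = titration.ratio_x
    a = titration.activity_pct / 100.0
    lo, hi = window
    sel = (a >= lo) & (a <= hi)
    if np.sum(sel) < 3:
        near_full = np.sum(a > hi)
        near_zero = np.sum(a < lo)
        raise RangeError(
            f"only {int(np.sum(sel))} points in the {lo:.0%}-{hi:.0%} activity "
            f"window ({near_full} near control, {near_zero} near zero); widen "
            "the load-ratio grid around the zero-activity onset"
        )
    res = stats.linregress(x[sel], a[sel])
    if res.slope >= 0:
        raise RangeError("no descending linear region: fitted slope is >= 0")
    x0 = -res.intercept / res.slope
    # delta-method propagation of the intercept x0 = -b/m
    if res.stderr and res.intercept_stderr is not None:
        var = (res.intercept_stderr / res.slope) ** 2 + (
            res.intercept * res.stderr / res.slope**2) ** 2
        stderr = float(np.sqrt(var))
    else:
        stderr = None
    censored = not bool(np.any(a[titration.complete] <= lo))
    return PartitionEstimate(r=float(x0 - 1.0), r_stderr=stderr,
                             intercept_x=float(x0),
                             n_points_used=int(np.sum(sel)),
                             censored=censored)


def titrate_active_sites(
    low_r_rates: RateSet,
    I0_grid,
    nominal_E: float,
    max_time: float = 14400.0,
) -> float:
    """Active-site titration: functional enzyme molarity (uM).

    A low partition-ratio inactivator (r < 5) consumes (r+1) molecules
    per site, so the zero-activity intercept of the titration, in
    concentration units, divided by (r+1) is the active-site molarity.
    ``nominal_E`` seeds the simulation; the returned value is what the
    endpoint actually reports.
    """
    dp = derive_kitz_wilson(low_r_rates)
    if not dp.is_inactivating or dp.r >= 5:
        raise ValidationError(
            f"active-site titration needs an inactivator with r < 5 "
            f"(preset has r = {dp.r:g})"
        )
    tit = titrate_to_completion(low_r_rates, nominal_E, I0_grid, max_time)
    est = estimate_partition(tit)
    # intercept in concentration units is (r+1) * E_active
    return est.intercept_x * nominal_E / (dp.r + 1.0)


def design_titration_grid(r_guess: float, E0: float, n: int = 10) -> np.ndarray:
    """Ten log-spaced inhibitor loads bracketing the zero-activity onset.

    Ratios span 0.2*(r_guess+1) to 2*(r_guess+1); returned as I0 in uM.
    """
    if r_guess < 0 or E0 <= 0:
        raise ValidationError("r_guess >= 0 and E0 > 0 required")
    onset = r_guess + 1.0
    ratios = np.geomspace(0.2 * onset, 2.0 * onset, n)
    return ratios * E0
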