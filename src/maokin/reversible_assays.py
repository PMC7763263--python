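"""No-preincubation (reversible) inhibition assays.

Initial binding of a mechanism-based inactivator is competitive:

    v = kcat * E * S / (KM * (1 + I/Ki) + S)

IC50 measured at fixed substrate follows the Cheng-Prusoff relation
IC50 = Ki * (1 + S/KM); at the standard assay condition S = 2*KM this is
exactly 3*Ki.  Dose-response curves are fitted with bottom fixed at 0
and Hill slope fixed at 1 (top and IC50 free), and Ki comes from a
global competitive Michaelis-Menten fit sharing Vmax, KM and Ki across
a substrate x inhibitor initial-rate grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError
from .kinetic_core import SubstrateParams


@dataclass
class DoseResponse:
    """Fractional initial rates (control = 1) vs inhibitor concentration."""

    conc_uM: np.ndarray
    rate_frac: np.ndarray
    substrate: SubstrateParams | None = None

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.rate_frac = np.asarray(self.rate_frac, dtype=float)
        if self.conc_uM.shape != self.rate_frac.shape:
            raise ValidationError("conc_uM and rate_frac must have equal shape")
        if np.any(self.conc_uM < 0):
            raise ValidationError("inhibitor concentrations must be >= 0")
        if not np.any(self.conc_uM == 0):
            raise ValidationError("a zero-inhibitor control point is required")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   substrate: SubstrateParams | None = None) -> "DoseResponse":
        return cls(df["conc_uM"].to_numpy(), df["rate"].to_numpy(), substrate)


@dataclass(frozen=True)
class IC50Fit:
    IC50: float
    top: float
    hill: float
    residual_norm: float
    IC50_stderr: float | None = None


@dataclass(frozen=True)
class KiFit:
    Ki: float
    Vmax: float
    KM: float
    Ki_stderr: float | None
    Vmax_stderr: float | None
    KM_stderr: float | None
    residual_norm: float


def initial_rate(E: float, substrate: SubstrateParams, I: float, Ki: float) -> float:
    """Competitive-inhibition initial rate v (uM/min).

    v = kcat*E*S / (KM*(1 + I/Ki) + S).
    """
    if E < 0 or I < 0:
        raise ValidationError("E and I must be >= 0")
    if Ki <= 0:
        raise ValidationError(f"Ki must be > 0, got {Ki}")
    return substrate.kcat * E * substrate.S / (
        substrate.KM * (1.0 + I / Ki) + substrate.S
    )


def fit_ic50(data: DoseResponse) -> IC50Fit:
    """Fit v/v0 = top / (1 + I/IC50), bottom = 0, Hill slope = 1.

    IC50 is initialized at the tested concentration whose response is
    nearest half the control response.  Raises :class:`RangeError` if the
    measured responses never cross 50% of control within the tested
    concentration range.
    """
    conc, frac = data.conc_uM, data.rate_frac
    if conc.size < 5:
        raise ValidationError("at least 5 concentrations are required")
    top0 = float(np.mean(frac[conc == 0]))
    if np.min(frac) > 0.5 * top0:
        below = conc[frac < 0.5 * top0]
        hi = float(np.max(conc))
        raise RangeError(
            f"no 50% crossing within tested range: responses stay above "
            f"{0.5 * top0:.3g} up to {hi:g} uM"
            + ("" if below.size else " (increase the top concentration)")
        )

    nz = conc > 0
    ic50_0 = float(conc[nz][np.argmin(np.abs(frac[nz] - 0.5 * top0))])

    model = lmfit.Model(lambda I, top, ic50: top / (1.0 + I / ic50),
                        independent_vars=["I"])
    params = model.make_params(top=top0, ic50=max(ic50_0, 1e-9))
    params["ic50"].set(min=1e-12)
    params["top"].set(min=1e-6)
    result = model.fit(frac, params, I=conc)
    return IC50Fit(
        IC50=float(result.params["ic50"].value),
        top=float(result.params["top"].value),
        hill=1.0,
        residual_norm=float(np.linalg.norm(result.residual)),
        IC50_stderr=(float(result.params["ic50"].stderr)
                     if result.params["ic50"].stderr is not None else None),
    )


def fit_ki_global(rates: pd.DataFrame) -> KiFit:
    """Global competitive Michaelis-Menten fit over an S x I rate grid.

    Parameters
    ----------
    rates : DataFrame
        Columns ``S_uM``, ``I_uM``, ``v`` — initial rates (uM/min) on a
        substrate x inhibitor grid including the I = 0 control column.
        A single Vmax, KM and Ki are shared across all points.
    """
    for col in ("S_uM", "I_uM", "v"):
        if col not in rates.columns:
            raise ValidationError(f"rates frame must contain column {col!r}")
    S = rates["S_uM"].to_numpy(dtype=float)
    I = rates["I_uM"].to_numpy(dtype=float)
    v = rates["v"].to_numpy(dtype=float)
    if not np.any(I == 0):
        raise ValidationError("the grid must include an I = 0 control column")

    # starting values from the control column (Lineweaver-free heuristics)
    ctrl = I == 0
    vmax0 = float(np.max(v[ctrl]) * 1.5)
    km0 = float(np.median(S))
    ki0 = float(np.median(I[~ctrl])) if np.any(~ctrl) else 1.0

    def model(params):
        Vmax, KM, Ki = params["Vmax"], params["KM"], params["Ki"]
        return Vmax * S / (KM * (1.0 + I / Ki) + S) - v

    params = lmfit.Parameters()
    params.add("Vmax", value=vmax0, min=1e-12)
    params.add("KM", value=km0, min=1e-12)
    params.add("Ki", value=max(ki0, 1e-6), min=1e-12)
    result = lmfit.minimize(model, params)

    ki = result.params["Ki"]
    if ki.stderr is not None and ki.stderr > ki.value:
        warnings.warn(
            "Ki is poorly determined (stderr exceeds estimate); the inhibitor "
            "grid may lie far below Ki", stacklevel=2,
        )
    return KiFit(
        Ki=float(ki.value),
        Vmax=float(result.params["Vmax"].value),
        KM=float(result.params["KM"].value),
        Ki_stderr=None if ki.stderr is None else float(ki.stderr),
        Vmax_stderr=(None if result.params["Vmax"].stderr is None
                     else float(result.params["Vmax"].stderr)),
        KM_stderr=(None if result.params["KM"].stderr is None
                   else float(result.params["KM"].stderr)),
        residual_norm=float(np.linalg.norm(result.residual)),
    )


def cheng_prusoff_ic50(Ki: float, substrate: SubstrateParams) -> float:
    """Competitive-inhibition IC50 = Ki * (1 + S/KM)."""
    if Ki <= 0:
        raise ValidationError("Ki must be > 0")
    return Ki * substrate.protection_factor
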