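"""Shared fixtures and the independent fixed-step integrator oracle."""

import numpy as np
import pytest

from maokin import RateSet, make_preset_library
from maokin.synthetic_data import NoiseModel


def rk4_oracle(rates: RateSet, E0: float, I0: float, t_end: float,
               dt: float = 1e-4, aerobic: bool = True):
    """Fixed-step RK4 integration of the inactivation scheme.

    Written directly from the mass-action equations, independent of the
    package's adaptive integrator; used as the ground-truth oracle for
    trajectory values.  Returns (times, states matrix) with states in the
    order E_ox, EI, EIstar, E_adduct, E_red, I_free, P.
    """
    kon, koff, kox, krel, kchem = (rates.k_on, rates.k_off, rates.k_ox,
                                   rates.k_rel, rates.k_chem)

    def f(y):
        E, EI, EIs, Ead, Ered, I, P = y
        b = kon * E * I
        u = koff * EI
        ox = kox * EI
        rel = krel * EIs
        ad = kchem * EIs
        return np.array([
            -b + u + (rel if aerobic else 0.0),
            b - u - ox,
            ox - rel - ad,
            ad,
            0.0 if aerobic else rel,
            -b + u,
            rel,
        ])

    n = int(round(t_end / dt))
    y = np.array([E0, 0, 0, 0, 0, I0, 0], dtype=float)
    times = np.empty(n + 1)
    states = np.empty((n + 1, 7))
    times[0], states[0] = 0.0, y
    for i in range(n):
        k1 = f(y)
        k2 = f(y + dt / 2 * k1)
        k3 = f(y + dt / 2 * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        times[i + 1], states[i + 1] = (i + 1) * dt, y
    return times, states


@pytest.fixture(scope="session")
def library():
    return make_preset_library()


@pytest.fixture(scope="session")
def presets(library):
    return {p.key: p for p in library}


@pytest.fixture()
def nonoise():
    return NoiseModel(sigma_additive=0.0, sigma_multiplicative=0.0, seed=0)


def qss_rate_grid():
    """Rate sets in the regime where the Kitz-Wilson closed forms are
    exact: binding pre-equilibrates (k_off >> k_ox) and the oxidized-
    product complex drains fast ((k_rel + k_chem) >> k_ox)."""
    grid = []
    for k_ox in (0.5, 2.0, 10.0):
        for r in (0.0, 1.0, 4.0):
            for Ki in (0.5, 5.0):
                k_chem = 100.0 * k_ox / (r + 1.0)
                k_off = 1000.0 * k_ox
                grid.append(RateSet(k_on=k_off / Ki, k_off=k_off, k_ox=k_ox,
                                    k_rel=r * k_chem, k_chem=k_chem))
    return grid
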