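"""Shared fixtures: default stacks, geometries and simulated curves.

Session-scoped because the noiseless Fresnel curves and their fits are
deterministic and reused across many tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import sprfit as sp

WATER_START = 60.5
AIR_START = 38.0
RAMP_START = 61.0


def parratt_reflectance(n_list, d_list, wavelength_nm, theta_deg, pol):
    """Independent oracle: recursive Fresnel-coefficient (Parratt) reflectance.

    Deliberately a different algorithm from the package's characteristic
    matrix: interface r-coefficients combined bottom-up with phase factors.
    ``n_list`` is [prism, layer1, ..., bulk]; ``d_list`` aligns with n_list
    (entries for the two half-spaces are ignored).
    """
    k0 = 2 * np.pi / wavelength_nm
    beta = n_list[0] * np.sin(np.radians(theta_deg))
    kz = []
    for n in n_list:
        k = k0 * np.emath.sqrt(n**2 - beta**2)
        kz.append(-k if np.ndim(k) == 0 and k.imag < 0 else k)

    def r_ij(i, j):
        if pol == "TE":
            return (kz[i] - kz[j]) / (kz[i] + kz[j])
        qi, qj = kz[i] / n_list[i] ** 2, kz[j] / n_list[j] ** 2
        return (qi - qj) / (qi + qj)

    m = len(n_list)
    r = r_ij(m - 2, m - 1)
    for i in range(m - 3, -1, -1):
        phase = np.exp(2j * kz[i + 1] * d_list[i + 1])
        rn = r_ij(i, i + 1)
        r = (rn + r * phase) / (1 + rn * r * phase)
    return np.abs(r) ** 2


def stack_to_lists(stack: sp.OpticalStack):
    n_list = [stack.prism_index] + [n for n, _ in stack.layers] + [stack.bulk_index]
    d_list = [0.0] + [d for _, d in stack.layers] + [0.0]
    return n_list, d_list


@pytest.fixture(scope="session")
def water_stack():
    return sp.kretschmann_stack(bulk_index=1.333)


@pytest.fixture(scope="session")
def air_stack():
    return sp.kretschmann_stack(bulk_index=1.000)


@pytest.fixture(scope="session")
def water_geometry():
    return sp.default_geometry(start_deg=WATER_START)


@pytest.fixture(scope="session")
def air_geometry():
    return sp.default_geometry(start_deg=AIR_START)


@pytest.fixture(scope="session")
def water_curve(water_stack, water_geometry):
    return sp.simulate_spr_curve(water_stack, water_geometry)


@pytest.fixture(scope="session")
def air_curve(air_stack, air_geometry):
    return sp.simulate_spr_curve(air_stack, air_geometry)


@pytest.fixture(scope="session")
def water_fit(water_curve):
    return sp.fit_curve(water_curve, "sigmoid_asymmetric")


@pytest.fixture(scope="session")
def air_fit(air_curve):
    return sp.fit_curve(air_curve, "sigmoid_asymmetric")
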