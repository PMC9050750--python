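"""Shared fixtures and independent numerical oracles.

The oracles here deliberately re-derive results through routes that do
not share code with the package: a damped fixed-point iteration of the
steady-state balance equations, and a brute-force enumeration of the
rank-sum null distribution.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from epipump import ActiveFluxSpec, BathConditions, DeviceGeometry, EpitheliumParams
from epipump.cli_io import load_reference


@pytest.fixture(scope="session")
def mdck_reference():
    return load_reference("mdck_normal")


@pytest.fixture(scope="session")
def cystic_reference():
    return load_reference("adpkd_cystic")


@pytest.fixture(scope="session")
def oracle_params():
    """Parameter set of the hand-derived closed-form stall example."""
    return EpitheliumParams(
        L_a=3e-10, L_b=3e-10, K_s=3e-10,
        g_a=2.4e-5, g_b=2.4e-5, k_d=2e-5,
        active=ActiveFluxSpec(variant="constant", A0=2.5e-6),
    )


@pytest.fixture(scope="session")
def isotonic():
    return BathConditions(c_a=300.0, c_b=300.0)


@pytest.fixture(scope="session")
def geometry():
    return DeviceGeometry()


def fixed_point_steady_state(params, baths, damping=0.5, max_iter=200_000, tol=1e-14):
    """Damped fixed-point iteration of the steady-state balances.

    Independent of the package solver: cycles cell solute balance ->
    cleft solute balance -> summed water equations until the relative
    update falls below ``tol``.  Constant active-flux variant only.
    """
    assert params.active.variant == "constant"
    s = 1.0 if params.orientation == "absorptive" else -1.0
    a = s * params.active.A0
    rts = params.RT * params.sigma_r
    L = 1.0 / (1.0 / params.L_a + 1.0 / params.L_b + 1.0 / params.K_s)
    c_c, c_s, J = baths.c_a, baths.c_b, 0.0
    for _ in range(max_iter):
        c_c_new = (params.g_a * baths.c_a + params.g_b * c_s) / (params.g_a + params.g_b)
        c_s_new = (params.g_b * c_c_new + a + params.k_d * baths.c_b) / (
            params.g_b + params.k_d + J
        )
        J_new = L * ((baths.P_a - baths.P_b) + rts * (c_s_new - baths.c_a))
        c_c_next = (1 - damping) * c_c + damping * c_c_new
        c_s_next = (1 - damping) * c_s + damping * c_s_new
        J_next = (1 - damping) * J + damping * J_new
        delta = max(
            abs(c_c_next - c_c) / max(abs(c_c_next), 1e-30),
            abs(c_s_next - c_s) / max(abs(c_s_next), 1e-30),
            abs(J_next - J) / max(abs(J_next), 1e-30),
        )
        c_c, c_s, J = c_c_next, c_s_next, J_next
        if delta < tol:
            break
    else:
        raise RuntimeError("fixed-point oracle did not converge")
    P_s = baths.P_b + J / params.K_s
    P_c = P_s + J / params.L_b + rts * (c_c - c_s)
    return c_c, P_c, c_s, P_s, J


def exact_ranksum_two_sided_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of label arrangements."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    combined = x + y
    u_obs = sum(xi > yj for xi in x for yj in y) + 0.5 * sum(
        xi == yj for xi in x for yj in y
    )
    center = n * m / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(n + m) if i not in idx]
        u = sum(a > b for a in xs for b in ys) + 0.5 * sum(a == b for a in xs for b in ys)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total
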