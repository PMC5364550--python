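"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the titration steady state
is obtained by numerically integrating the two-species kinetic ODE system (and
polishing the endpoint with a generic root finder on the ODE right-hand side),
and the rank statistics are computed with plain-Python sorting and the textbook
formulas.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve
from scipy.stats import chi2


def ode_rhs(kp):
    """Right-hand side of the two-species system (free mRNA r, complex rs)."""

    def rhs(_, y):
        r, rs = y
        m_free = kp.m_total - rs
        bind = kp.k_on * m_free * r
        return [
            kp.k_R - kp.gamma_r * r - bind + kp.k_off * rs,
            bind - (kp.k_off + kp.gamma_star) * rs,
        ]

    return rhs


def ode_equilibrium(kp) -> tuple[float, float]:
    """Long-time limit of the kinetic ODEs, Newton-polished on the RHS."""
    rhs = ode_rhs(kp)
    rates = [kp.gamma_r, kp.gamma_star + kp.k_off]
    if kp.m_total > 0:
        rates.append(kp.k_on * kp.m_total)
    t_end = 50.0 / min(r for r in rates if r > 0)
    r0_free = kp.k_R / kp.gamma_r
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [r0_free, 0.0],
        method="Radau",
        rtol=1e-10,
        atol=1e-12 * max(r0_free, kp.m_total, 1.0),
    )
    y_end = sol.y[:, -1]
    polished = fsolve(lambda y: rhs(0.0, y), y_end, xtol=1e-12)
    return float(polished[0]), float(polished[1])


def kinetic_from_reduced(r0: float, theta: float, lam: float):
    """One kinetic parameterization realizing given reduced parameters.

    gamma_r = gamma_star = 1 gives theta = m_total and r0 = k_R; with
    k_off = 1, lam = (1 + 1)/k_on fixes k_on = 2/lam (lam must be > 0).
    """
    from utakit import KineticParams

    if lam <= 0:
        raise ValueError("use lam > 0 for the ODE oracle construction")
    return KineticParams(
        k_R=r0, gamma_r=1.0, k_on=2.0 / lam, k_off=1.0, gamma_star=1.0, m_total=theta
    )


def ode_steady_state_r(r0: float, theta: float, lam: float) -> float:
    """ODE-oracle value of the steady-state free mRNA for reduced parameters."""
    return ode_equilibrium(kinetic_from_reduced(r0, theta, lam))[0]


# ---------------------------------------------------------------------------
# rank statistics (pure Python)


def plain_ranks(values) -> list[float]:
    """Midranks computed with explicit sorting and tie averaging."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def brute_force_kruskal(groups: dict) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p from first principles."""
    pooled = [float(v) for g in groups.values() for v in g]
    n = len(pooled)
    ranks = plain_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups.values():
        size = len(g)
        rbar = sum(ranks[start : start + size]) / size
        h += size * rbar * rbar
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction divisor
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    denom = 1.0 - tie / (n**3 - n) if n > 1 else 1.0
    if denom == 0.0:
        return 0.0, 1.0
    h /= denom
    p = float(chi2.sf(h, len(groups) - 1))
    return h, p


def brute_force_dunn_z(groups: dict, a: str, b: str) -> float:
    """Dunn's z for one pair, from pooled midranks and the textbook SE."""
    pooled = [float(v) for g in groups.values() for v in g]
    n = len(pooled)
    ranks = plain_ranks(pooled)
    mean_rank = {}
    start = 0
    for name, g in groups.items():
        size = len(g)
        mean_rank[name] = sum(ranks[start : start + size]) / size
        start += size
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    se = math.sqrt(var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
    return (mean_rank[a] - mean_rank[b]) / se
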