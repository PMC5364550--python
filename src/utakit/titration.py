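"""Molecular-titration model of miRNA-mediated repression.

The model tracks a target mRNA that is transcribed at rate ``k_R``, decays at
rate ``gamma_r`` while free, and is reversibly sequestered by a miRNA pool of
constant total concentration ``m_total`` into a translationally silent complex
(association ``k_on``, dissociation ``k_off``, complex degradation
``gamma_star``).  At steady state the whole system collapses to two effective
parameters,

* ``theta`` — effective miRNA abundance, ``(gamma_star / gamma_r) * m_total``;
  sets the position of the repression threshold, and
* ``lam`` — effective dissociation constant, ``(k_off + gamma_star) / k_on``;
  its inverse is the binding capability and sets threshold sharpness,

both expressed in the same arbitrary reporter-intensity-equivalent units as the
unrepressed steady-state level ``r0 = k_R / gamma_r``.  The free (translatable)
mRNA at steady state is the unique non-negative root of

    r**2 + r*(lam + theta - r0) - lam*r0 = 0,

which interpolates between the threshold-linear law ``max(r0 - theta, 0)``
(perfect binding, ``lam = 0``) and the unrepressed identity ``r = r0``
(``lam -> inf`` or ``theta = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "ReducedParams",
    "ModelState",
    "reduce_params",
    "steady_state_r",
    "steady_state_complex",
    "steady_state",
    "simulate_dose_response",
    "simulate_grid",
]


@dataclass(frozen=True)
class KineticParams:
    """Full rate-constant parameterization of the two-species system.

    Parameters
    ----------
    k_R : float
        Transcription rate of the target mRNA (molecules / time).
    gamma_r : float
        Decay rate of free mRNA (1 / time); must be positive.
    k_on : float
        miRNA–mRNA association rate (1 / (conc · time)).
    k_off : float
        Complex dissociation rate (1 / time).
    gamma_star : float
        Degradation rate of the bound complex (1 / time).
    m_total : float
        Total miRNA concentration (free + in complex), held constant.
    """

    k_R: float
    gamma_r: float
    k_on: float
    k_off: float
    gamma_star: float
    m_total: float

    def __post_init__(self) -> None:
        for name in ("k_R", "gamma_r", "k_on", "k_off", "gamma_star", "m_total"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
        if self.gamma_r == 0:
            raise ValueError("gamma_r must be > 0: r0 = k_R/gamma_r is undefined at 0")
        if self.m_total > 0 and self.k_on == 0:
            raise ValueError(
                "k_on must be > 0 when m_total > 0: lam = (k_off+gamma_star)/k_on "
                "is undefined for k_on = 0"
            )


@dataclass(frozen=True)
class ReducedParams:
    """Effective two-parameter steady-state form of the titration model."""

    theta: float
    lam: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta) or self.theta < 0:
            raise ValueError(f"theta must be finite and >= 0, got {self.theta!r}")
        if not np.isfinite(self.lam) or self.lam < 0:
            raise ValueError(f"lam must be finite and >= 0, got {self.lam!r}")


@dataclass(frozen=True)
class ModelState:
    """Steady-state levels: unrepressed (r0), free (r) and bound (r_star) mRNA."""

    r0: float
    r: float
    r_star: float


def reduce_params(kp: KineticParams) -> tuple[ReducedParams, float]:
    """Collapse the kinetic parameterization to ``(theta, lam)`` plus ``r0``.

    Returns
    -------
    (ReducedParams, float)
        The effective parameters and the unrepressed steady state
        ``r0 = k_R / gamma_r``.
    """
    r0 = kp.k_R / kp.gamma_r
    theta = (kp.gamma_star / kp.gamma_r) * kp.m_total
    if kp.m_total > 0 or kp.k_on > 0:
        lam = (kp.k_off + kp.gamma_star) / kp.k_on if kp.k_on > 0 else 0.0
    else:
        # no miRNA and no binding: lam is irrelevant, pick the neutral limit
        lam = 0.0
    return ReducedParams(theta=theta, lam=lam), r0


def steady_state_r(r0, params: ReducedParams):
    """Steady-state free (translatable) mRNA for unrepressed level(s) ``r0``.

    Evaluates the closed-form positive root of the steady-state quadratic.
    ``lam == 0`` is handled as the exact threshold-linear branch
    ``max(r0 - theta, 0)``.  For ``r0 < theta + lam`` the algebraically
    equivalent form ``2*lam*r0 / ((theta + lam - r0) + sqrt(disc))`` is used to
    avoid catastrophic cancellation deep in the repressed regime.

    Accepts a scalar or array ``r0``; returns the same shape.
    """
    r0_arr = np.asarray(r0, dtype=float)
    if np.any(~np.isfinite(r0_arr)) or np.any(r0_arr < 0):
        raise ValueError("r0 must be finite and >= 0")
    theta, lam = params.theta, params.lam
    if lam == 0.0:
        r = np.maximum(r0_arr - theta, 0.0)
    else:
        a = r0_arr - theta - lam
        disc = np.sqrt(a * a + 4.0 * lam * r0_arr)
        with np.errstate(divide="ignore", invalid="ignore"):
            stable = 2.0 * lam * r0_arr / (disc - a)
        r = np.where(a >= 0.0, 0.5 * (a + disc), stable)
        r = np.where(r0_arr == 0.0, 0.0, r)
    if np.ndim(r0) == 0:
        return float(r)
    return r


def steady_state_complex(r0, params: ReducedParams):
    """Steady-state miRNA-bound mRNA in reduced units: ``r0 - r``, bounded by theta."""
    r = steady_state_r(r0, params)
    return np.asarray(r0, dtype=float) - r if np.ndim(r0) else float(r0) - r


def steady_state(r0: float, params: ReducedParams) -> ModelState:
    """Full steady state at a single ``r0``."""
    r = steady_state_r(r0, params)
    return ModelState(r0=float(r0), r=r, r_star=float(r0) - r)


def _validate_grid(r0_grid) -> np.ndarray:
    grid = np.asarray(r0_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("r0 grid must be non-empty")
    if np.any(grid <= 0):
        raise ValueError("r0 grid values must be positive")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("r0 grid must be strictly increasing")
    return grid


def simulate_dose_response(params: ReducedParams, r0_grid) -> pd.DataFrame:
    """Dose–response curve ``r(r0)`` on a strictly increasing positive grid.

    Returns a DataFrame with columns ``r0, r, theta, lam``.
    """
    grid = _validate_grid(r0_grid)
    r = steady_state_r(grid, params)
    return pd.DataFrame(
        {"r0": grid, "r": np.atleast_1d(r), "theta": params.theta, "lam": params.lam}
    )


def log_r0_grid(r0_min: float, r0_max: float, n_points: int = 200) -> np.ndarray:
    """Default log-spaced r0 grid matching the lognormal spread of transfection."""
    if r0_min <= 0 or r0_max <= r0_min:
        raise ValueError("need 0 < r0_min < r0_max")
    return np.logspace(np.log10(r0_min), np.log10(r0_max), n_points)


def simulate_grid(
    thetas: Sequence[float], inv_lams: Sequence[float], r0_grid
) -> pd.DataFrame:
    """Steady-state curves for every (theta, 1/lam) combination.

    ``inv_lams`` entries are binding capabilities ``1/lam``; ``numpy.inf`` is
    the sentinel for perfect binding (``lam = 0``).  Returns one labeled curve
    per combination (``len(thetas) * len(inv_lams)`` curves) with columns
    ``r0, r, theta, lam, curve_id``.
    """
    thetas = list(thetas)
    inv_lams = list(inv_lams)
    if not thetas or not inv_lams:
        raise ValueError("thetas and inv_lams must be non-empty")
    grid = _validate_grid(r0_grid)
    frames = []
    for theta in thetas:
        for inv_lam in inv_lams:
            if not inv_lam > 0:
                raise ValueError("1/lam entries must be > 0 (use numpy.inf for lam=0)")
            lam = 0.0 if np.isinf(inv_lam) else 1.0 / inv_lam
            params = ReducedParams(theta=theta, lam=lam)
            curve = simulate_dose_response(params, grid)
            curve["curve_id"] = f"theta={theta:g}|inv_lam={inv_lam:g}"
            frames.append(curve)
    return pd.concat(frames, ignore_index=True)
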