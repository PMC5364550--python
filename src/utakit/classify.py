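"""Ordinal functional classification (low / mid / high) of fitted curves.

The repression ratio rho(x) = r(10**x) / 10**x is evaluated on the observed
log10 reference-intensity range [L, U].  rho is increasing in x, so its
minimum sits at L.  A curve whose ratio never drops below ``low_cutoff`` shows
no detectable threshold (low functional).  Otherwise the position where rho
first reaches 0.5, expressed as a fraction p of the log range, separates mid
(threshold resolved early, p < ``high_cutoff``) from high (threshold persists
into high intensities, p >= ``high_cutoff``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .titration import ReducedParams, steady_state_r

__all__ = ["FunctionalCall", "classify", "classify_curve"]

CATEGORIES = ("low", "mid", "high")


@dataclass(frozen=True)
class FunctionalCall:
    """Category plus the shape statistics it was derived from."""

    category: str
    min_repression_ratio: float
    crossing_position: float | None  # fraction of log range; None for 'low'


def classify_curve(
    theta: float,
    lam: float,
    x_range: tuple[float, float],
    low_cutoff: float = 0.75,
    high_cutoff: float = 0.5,
    n_grid: int = 1024,
) -> FunctionalCall:
    """Classify a titration curve given its parameters and a log10 r0 range."""
    L, U = float(x_range[0]), float(x_range[1])
    if not U > L:
        raise ValueError(f"need U > L in x_range, got ({L}, {U})")
    params = ReducedParams(theta, lam)
    xs = np.linspace(L, U, n_grid)
    r0 = 10.0 ** xs
    rho = steady_state_r(r0, params) / r0
    min_rho = float(np.min(rho))
    if min_rho >= low_cutoff:
        return FunctionalCall("low", min_rho, None)
    if rho[0] >= 0.5:
        x_cross = L
    elif rho[-1] < 0.5:
        x_cross = U
    else:
        x_cross = float(np.interp(0.5, rho, xs))  # rho is increasing in x
    p = float(np.clip((x_cross - L) / (U - L), 0.0, 1.0))
    category = "high" if p >= high_cutoff else "mid"
    return FunctionalCall(category, min_rho, p)


def classify(
    fit,
    x_range: tuple[float, float] | None = None,
    low_cutoff: float = 0.75,
    high_cutoff: float = 0.5,
) -> FunctionalCall:
    """Classify a converged :class:`~utakit.fitting.TransferFitResults`.

    ``x_range`` defaults to the span of the fitted transfer function's bins.
    """
    if not getattr(fit, "converged", True):
        raise ValueError("cannot classify a non-converged fit")
    if x_range is None:
        x_range = fit.model.tf.x_range
    return classify_curve(
        fit.theta, fit.lam, x_range, low_cutoff=low_cutoff, high_cutoff=high_cutoff
    )
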