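"""Synthetic dual-fluorescence cytometry event generator.

Emulates the single-plasmid dual-reporter transfection experiment: each cell
receives a lognormally distributed plasmid copy number (a fraction stays
untransfected), the reference channel (YFP-like) reads out the unrepressed
transcription level r0 and the reporter channel (CFP-like) reads out the
titration-model steady state r(r0; theta, lam).  Both channels carry
multiplicative lognormal measurement noise and an additive truncated-normal
autofluorescence floor.

Also provides the effective-parameter helpers for the experimental
perturbations: target-site copy number scales binding capability (1/lam)
linearly, with a bulged site counted as 0.2 copy equivalents, and an excess of
co-transfected siRNA competes endogenous miRNAs out of the silencing machinery,
reducing theta hyperbolically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .titration import ReducedParams, steady_state_r

__all__ = [
    "SimulationConfig",
    "BULGED_COPY_EQUIVALENT",
    "simulate_events",
    "effective_lambda",
    "effective_theta_competition",
    "write_events",
    "read_events",
]

#: copy-number equivalent assigned to a bulged (imperfectly paired) target site
BULGED_COPY_EQUIVALENT = 0.2

EVENT_COLUMNS = ["event_id", "sample_id", "ref_intensity", "rep_intensity"]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic cytometry sample.

    ``seed`` is required: every draw is deterministic given (config, seed).
    Intensity units are arbitrary; with the default unit gains the reference
    channel equals the plasmid copy number up to noise and autofluorescence.
    """

    seed: int
    theta: float = 100.0
    lam: float = 10.0
    n_events: int = 50_000
    copy_log_mean: float = math.log(100.0)
    copy_log_sd: float = 1.0
    untransfected_fraction: float = 0.2
    gain_ref: float = 1.0
    gain_rep: float = 1.0
    meas_log_sd: float = 0.15
    af_mean: float = 50.0
    af_sd: float = 10.0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required (no silent default)")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        for name in ("copy_log_sd", "meas_log_sd", "af_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.untransfected_fraction <= 1.0:
            raise ValueError("untransfected_fraction must be in [0, 1]")
        if self.gain_ref <= 0 or self.gain_rep <= 0:
            raise ValueError("channel gains must be > 0")
        if self.af_mean < 0:
            raise ValueError("af_mean must be >= 0")
        # validates theta/lam
        ReducedParams(self.theta, self.lam)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown SimulationConfig fields: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("seed is required (no silent default)")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated at 0 from below; degenerate when sd == 0."""
    if sd == 0.0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_events(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw one event table (one row per cell) under the titration model.

    Per event: plasmid copies C ~ lognormal(copy_log_mean, copy_log_sd), set to
    zero with probability ``untransfected_fraction``; r0 = C;
    ref = gain_ref * r0 * exp(eps_ref) + AF and
    rep = gain_rep * r(r0) * exp(eps_rep) + AF with independent
    eps ~ Normal(0, meas_log_sd) per channel and AF ~ Normal(af_mean, af_sd)
    truncated at 0, drawn independently per channel.
    """
    n = cfg.n_events
    rng = np.random.default_rng(cfg.seed)
    transfected = rng.random(n) >= cfg.untransfected_fraction
    copies = np.exp(rng.normal(cfg.copy_log_mean, cfg.copy_log_sd, n))
    copies[~transfected] = 0.0

    r0 = copies
    r = steady_state_r(r0, ReducedParams(cfg.theta, cfg.lam)) if n else np.empty(0)

    eps_ref = rng.normal(0.0, cfg.meas_log_sd, n) if cfg.meas_log_sd > 0 else np.zeros(n)
    eps_rep = rng.normal(0.0, cfg.meas_log_sd, n) if cfg.meas_log_sd > 0 else np.zeros(n)
    af_ref = _truncated_normal(rng, cfg.af_mean, cfg.af_sd, n)
    af_rep = _truncated_normal(rng, cfg.af_mean, cfg.af_sd, n)

    ref = cfg.gain_ref * r0 * np.exp(eps_ref) + af_ref
    rep = cfg.gain_rep * np.asarray(r) * np.exp(eps_rep) + af_rep

    return pd.DataFrame(
        {
            "event_id": np.arange(n, dtype=np.int64),
            "sample_id": cfg.sample_id,
            "ref_intensity": ref,
            "rep_intensity": rep,
        },
        columns=EVENT_COLUMNS,
    )


def effective_lambda(lam_single: float, copies: float) -> float:
    """Effective dissociation parameter for a reporter with ``copies`` target sites.

    Binding capability 1/lam scales linearly with the number of (perfect)
    target-site copies, so lam_eff = lam_single / copies.  A bulged site counts
    as ``BULGED_COPY_EQUIVALENT`` (0.2) copies.
    """
    if not copies > 0:
        raise ValueError(f"copies must be > 0, got {copies!r}")
    if not lam_single > 0:
        raise ValueError(f"lam_single must be > 0, got {lam_single!r}")
    return lam_single / copies


def effective_theta_competition(theta: float, sirna_dose: float, half_dose: float) -> float:
    """Effective miRNA abundance under competition by co-transfected siRNA.

    Hyperbolic saturation: theta / (1 + dose/half_dose) — equals theta at dose
    zero, halves at ``half_dose`` and vanishes in the excess limit.  Shifts the
    transfer function without changing threshold sharpness.
    """
    if not half_dose > 0:
        raise ValueError(f"half_dose must be > 0, got {half_dose!r}")
    if theta < 0 or sirna_dose < 0:
        raise ValueError("theta and sirna_dose must be >= 0")
    return theta / (1.0 + sirna_dose / half_dose)


def write_events(table: pd.DataFrame, path) -> None:
    """Write an event table as CSV (UTF-8, '.' decimal, bit-exact round trip)."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    table.loc[:, EVENT_COLUMNS].to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read an event table written by :func:`write_events`."""
    table = pd.read_csv(
        path,
        float_precision="round_trip",
        dtype={
            "event_id": np.int64,
            "sample_id": str,
            "ref_intensity": float,
            "rep_intensity": float,
        },
    )
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{Path(path)}: missing columns {missing}")
    return table.loc[:, EVENT_COLUMNS]
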