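"""Transfer-function construction from gated cytometry event tables.

A transfer function summarises the per-cell dose–response: log10 relative
reference intensity (relative to the gate value) is binned at fixed width
(default 0.05 decades, the cytometry convention for this assay) and the mean
log10 relative reporter intensity is computed per bin, keeping per-bin event
counts for later weighting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EmptyGateError",
    "TransferFunction",
    "gate_ref_positive",
    "compute_transfer_function",
    "write_transfer_function",
    "read_transfer_function",
]


class EmptyGateError(ValueError):
    """Raised when a gate removes every event."""


#: flooring applied after autofluorescence subtraction, as a fraction of the gate
FLOOR_FACTOR = 1e-6


@dataclass
class TransferFunction:
    """Binned log-reference vs mean log-reporter curve.

    ``bin_left``/``bin_center`` are log10 reference intensity relative to
    ``gate_value``; ``mean_log_rep`` is the per-bin mean log10 relative
    reporter intensity; ``sd_log_rep`` the per-bin sample standard deviation
    (0 for singleton bins).
    """

    bin_left: np.ndarray
    bin_center: np.ndarray
    mean_log_rep: np.ndarray
    n_events: np.ndarray
    gate_value: float
    bin_width: float
    sd_log_rep: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bin_left = np.asarray(self.bin_left, float)
        self.bin_center = np.asarray(self.bin_center, float)
        self.mean_log_rep = np.asarray(self.mean_log_rep, float)
        self.n_events = np.asarray(self.n_events, np.int64)
        if self.sd_log_rep is None:
            self.sd_log_rep = np.zeros_like(self.mean_log_rep)
        else:
            self.sd_log_rep = np.asarray(self.sd_log_rep, float)
        if not (
            len(self.bin_left)
            == len(self.bin_center)
            == len(self.mean_log_rep)
            == len(self.n_events)
            == len(self.sd_log_rep)
        ):
            raise ValueError("transfer-function columns must have equal length")
        if len(self.bin_center) > 1 and np.any(np.diff(self.bin_center) <= 0):
            raise ValueError("bin centers must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.bin_center)

    @property
    def x_range(self) -> tuple[float, float]:
        """Span of the observed log10 relative reference intensities."""
        return float(self.bin_left[0]), float(self.bin_left[-1] + self.bin_width)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_left,
                "bin_center": self.bin_center,
                "mean_log_rep": self.mean_log_rep,
                "n_events": self.n_events,
                "sd_log_rep": self.sd_log_rep,
            }
        )


def gate_ref_positive(
    events: pd.DataFrame,
    gate: float | None = None,
    control: pd.DataFrame | None = None,
    control_percentile: float = 99.0,
) -> pd.DataFrame:
    """Select reference-positive events (``ref_intensity > gate``).

    The gate is either given directly or derived from a control sample
    (typically untransfected cells) as a high percentile of its reference
    intensities.  The applied gate is recorded in ``result.attrs['gate_value']``.
    """
    if gate is None:
        if control is None:
            raise ValueError("provide either a gate value or a control sample")
        gate = float(np.percentile(control["ref_intensity"], control_percentile))
    if not gate > 0:
        raise ValueError(f"gate must be > 0, got {gate!r}")
    out = events[events["ref_intensity"] > gate].copy()
    if out.empty:
        raise EmptyGateError(f"no events survive the gate ref_intensity > {gate:g}")
    out.attrs["gate_value"] = float(gate)
    return out


def compute_transfer_function(
    events: pd.DataFrame,
    gate_value: float | None = None,
    bin_width: float = 0.05,
    min_events: int = 10,
    af_mean: float = 0.0,
) -> TransferFunction:
    """Bin gated events into a transfer function.

    x = log10(ref/gate) is assigned to half-open bins [k*w, (k+1)*w) (ties to
    the left edge via floor); y = log10(rep/gate); bins with fewer than
    ``min_events`` events are dropped.  If ``af_mean`` > 0 it is subtracted
    from both channels before relativization, flooring at 1e-6 * gate to keep
    logarithms finite.
    """
    if events.empty:
        raise ValueError("gated event table is empty")
    if gate_value is None:
        gate_value = events.attrs.get("gate_value")
    if gate_value is None or not gate_value > 0:
        raise ValueError("gate_value must be supplied (or recorded by gating)")
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")

    floor = FLOOR_FACTOR * gate_value
    ref = np.maximum(events["ref_intensity"].to_numpy(float) - af_mean, floor)
    rep = np.maximum(events["rep_intensity"].to_numpy(float) - af_mean, floor)

    x = np.log10(ref / gate_value)
    y = np.log10(rep / gate_value)
    k = np.floor(x / bin_width).astype(np.int64)

    grouped = pd.DataFrame({"k": k, "y": y}).groupby("k")["y"]
    stats_df = grouped.agg(["count", "mean", "std"]).reset_index()
    stats_df["std"] = stats_df["std"].fillna(0.0)
    stats_df = stats_df[stats_df["count"] >= min_events].sort_values("k")
    if stats_df.empty:
        raise ValueError(
            f"every bin has fewer than min_events={min_events} events; "
            "collect more events or increase bin_width"
        )
    kk = stats_df["k"].to_numpy()
    return TransferFunction(
        bin_left=kk * bin_width,
        bin_center=(kk + 0.5) * bin_width,
        mean_log_rep=stats_df["mean"].to_numpy(),
        n_events=stats_df["count"].to_numpy(),
        sd_log_rep=stats_df["std"].to_numpy(),
        gate_value=float(gate_value),
        bin_width=float(bin_width),
    )


def write_transfer_function(tf: TransferFunction, path) -> None:
    """CSV with a ``# gate=<value> bin_width=<w>`` comment header line."""
    buf = io.StringIO()
    buf.write(f"# gate={tf.gate_value!r} bin_width={tf.bin_width!r}\n")
    tf.to_frame().to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_transfer_function(path) -> TransferFunction:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# gate=... bin_width=...' header")
        meta = dict(item.split("=", 1) for item in header.lstrip("# ").split())
        frame = pd.read_csv(fh)
    return TransferFunction(
        bin_left=frame["bin_left"].to_numpy(),
        bin_center=frame["bin_center"].to_numpy(),
        mean_log_rep=frame["mean_log_rep"].to_numpy(),
        n_events=frame["n_events"].to_numpy(),
        sd_log_rep=frame.get("sd_log_rep", pd.Series(np.zeros(len(frame)))).to_numpy(),
        gate_value=float(meta["gate"]),
        bin_width=float(meta["bin_width"]),
    )
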