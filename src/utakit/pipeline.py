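"""End-to-end pipeline: simulate -> gate -> transfer -> fit -> classify -> compare.

Driven by a YAML config with one block per stage; a single required global
seed is expanded into fixed per-stage substreams so that stages rerun in
isolation reproduce the pipeline run bit for bit.  Every run writes a
machine-readable manifest (config hash, seed, package versions, outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify
from .cytometry import SimulationConfig, simulate_events, write_events
from .fitting import MeasurementNoise, fit_transfer_function
from .profiles import KruskalDunnResult, kruskal_dunn
from .transfer import compute_transfer_function, gate_ref_positive, write_transfer_function

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "plot_outputs"]

log = logging.getLogger("utakit.pipeline")

# fixed substream offsets: sample i simulates with seed + _SIM_STRIDE*(i+1),
# every fit uses seed + _FIT_OFFSET
_SIM_STRIDE = 1009
_FIT_OFFSET = 7


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    theta: float
    lam: float
    expression: float | None = None
    overrides: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    samples: tuple[SampleSpec, ...]
    simulation: dict = field(default_factory=dict)
    gate: float | None = None
    bin_width: float = 0.05
    min_events: int = 10
    subtract_af: bool = True
    fit_starts: int = 3
    fit_weights: str = "counts"
    fit_noise_aware: bool = False
    low_cutoff: float = 0.75
    high_cutoff: float = 0.5
    compare_adjust: str = "bonferroni"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ValueError("pipeline config must set a global seed")
        if not raw.get("samples"):
            raise ValueError("pipeline config must list at least one sample")
        samples = []
        for s in raw["samples"]:
            s = dict(s)
            samples.append(
                SampleSpec(
                    sample_id=str(s.pop("sample_id")),
                    theta=float(s.pop("theta")),
                    lam=float(s.pop("lam")),
                    expression=s.pop("expression", None),
                    overrides=s,
                )
            )
        fit_block = raw.get("fit", {})
        classify_block = raw.get("classify", {})
        compare_block = raw.get("compare", {})
        cfg = cls(
            seed=int(raw["seed"]),
            samples=tuple(samples),
            simulation=dict(raw.get("simulation", {})),
            gate=raw.get("gate"),
            bin_width=float(raw.get("bin_width", 0.05)),
            min_events=int(raw.get("min_events", 10)),
            subtract_af=bool(raw.get("subtract_af", True)),
            fit_starts=int(fit_block.get("starts", 3)),
            fit_weights=str(fit_block.get("weights", "counts")),
            fit_noise_aware=bool(fit_block.get("noise_aware", False)),
            low_cutoff=float(classify_block.get("low_cutoff", 0.75)),
            high_cutoff=float(classify_block.get("high_cutoff", 0.5)),
            compare_adjust=str(compare_block.get("adjust", "bonferroni")),
        )
        # validate every sample's simulation block eagerly, before any work
        for i, spec in enumerate(cfg.samples):
            cfg.sim_config(i)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sim_config(self, index: int) -> SimulationConfig:
        spec = self.samples[index]
        fields = dict(self.simulation)
        fields.update(spec.overrides)
        fields.update(
            seed=self.seed + _SIM_STRIDE * (index + 1),
            theta=spec.theta,
            lam=spec.lam,
            sample_id=spec.sample_id,
        )
        return SimulationConfig.from_dict(fields)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "theta": s.theta,
                    "lam": s.lam,
                    "expression": s.expression,
                    **s.overrides,
                }
                for s in self.samples
            ],
            "simulation": self.simulation,
            "gate": self.gate,
            "bin_width": self.bin_width,
            "min_events": self.min_events,
            "subtract_af": self.subtract_af,
            "fit": {
                "starts": self.fit_starts,
                "weights": self.fit_weights,
                "noise_aware": self.fit_noise_aware,
            },
            "classify": {"low_cutoff": self.low_cutoff, "high_cutoff": self.high_cutoff},
            "compare": {"adjust": self.compare_adjust},
        }


@dataclass
class PipelineReport:
    outdir: Path
    fit_table: pd.DataFrame
    comparison: KruskalDunnResult | None
    manifest: dict
    transfer_functions: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    pass


def _stage(name: str, sample_id: str | None = None):
    label = f"{name}[{sample_id}]" if sample_id else name
    return label


def run_pipeline(cfg: PipelineConfig, outdir) -> PipelineReport:
    """Run every stage for every sample and write the report bundle.

    Identical config + seed produce byte-identical CSV outputs.  Stage errors
    are re-raised annotated with the stage name and sample id.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    outputs = []
    tfs, fits = {}, {}
    for i, spec in enumerate(cfg.samples):
        sid = spec.sample_id
        try:
            t0 = time.perf_counter()
            sim_cfg = cfg.sim_config(i)
            events = simulate_events(sim_cfg)
            events_path = outdir / f"events_{sid}.csv"
            write_events(events, events_path)
            outputs.append(events_path.name)
            log.info("%s: %d events (%.2fs)", _stage("simulate", sid), len(events), time.perf_counter() - t0)

            gate = cfg.gate
            if gate is None:
                # default: safely above the autofluorescence floor
                gate = sim_cfg.af_mean + 5.0 * sim_cfg.af_sd
            gated = gate_ref_positive(events, gate=gate)
            tf = compute_transfer_function(
                gated,
                bin_width=cfg.bin_width,
                min_events=cfg.min_events,
                af_mean=sim_cfg.af_mean if cfg.subtract_af else 0.0,
            )
            tf_path = outdir / f"tf_{sid}.csv"
            write_transfer_function(tf, tf_path)
            outputs.append(tf_path.name)
            tfs[sid] = tf

            noise = MeasurementNoise.from_simulation(sim_cfg) if cfg.fit_noise_aware else None
            fit = fit_transfer_function(
                tf,
                weights=cfg.fit_weights,
                starts=cfg.fit_starts,
                seed=cfg.seed + _FIT_OFFSET,
                noise=noise,
            )
            fits[sid] = fit
            call = classify(fit, low_cutoff=cfg.low_cutoff, high_cutoff=cfg.high_cutoff)
            row = {"sample_id": sid, **fit.to_dict()}
            row["flags"] = ";".join(fit.flags)
            row["category"] = call.category
            row["min_rho"] = call.min_repression_ratio
            row["crossing_p"] = call.crossing_position
            row["expression"] = spec.expression
            rows.append(row)
        except Exception as exc:
            raise PipelineError(f"stage failure in sample {sid!r}: {exc}") from exc

    fit_table = pd.DataFrame(rows)
    report_path = outdir / "fit_report.csv"
    fit_table.to_csv(report_path, index=False)
    outputs.append(report_path.name)

    comparison = None
    expr = fit_table.dropna(subset=["expression"]) if "expression" in fit_table else pd.DataFrame()
    if not expr.empty and expr["category"].nunique() >= 2:
        groups = {
            cat: sub["expression"].to_numpy() for cat, sub in expr.groupby("category")
        }
        comparison = kruskal_dunn(groups, adjust=cfg.compare_adjust)
        comp_path = outdir / "comparison.csv"
        comparison.pairwise.assign(
            h_statistic=comparison.h_statistic, h_pvalue=comparison.pvalue
        ).to_csv(comp_path, index=False)
        outputs.append(comp_path.name)

    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {
            "utakit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineReport(
        outdir=outdir,
        fit_table=fit_table,
        comparison=comparison,
        manifest=manifest,
        transfer_functions=tfs,
        fits=fits,
    )


def plot_outputs(report: PipelineReport, formats=("png",)) -> list[Path]:
    """Export the standard figure set for a report bundle; warn-and-continue."""
    from .cytometry import read_events
    from .plots import plot_events_scatter, plot_params_vs_expression, plot_transfer_fits

    written: list[Path] = []
    if report.fit_table.empty:
        warnings.warn("empty report bundle: nothing to plot")
        return written

    def _save(fig, stem):
        for ext in formats:
            path = report.outdir / f"{stem}.{ext}"
            try:
                fig.savefig(path, dpi=120)
                written.append(path)
            except Exception as exc:  # pragma: no cover
                warnings.warn(f"could not write {path}: {exc}")

    for sid in report.fit_table["sample_id"]:
        events_path = report.outdir / f"events_{sid}.csv"
        if events_path.exists():
            try:
                fig = plot_events_scatter(read_events(events_path), title=sid)
                _save(fig, f"scatter_{sid}")
            except Exception as exc:
                warnings.warn(f"scatter plot failed for {sid}: {exc}")
    items = [
        (sid, report.transfer_functions[sid], report.fits.get(sid))
        for sid in report.transfer_functions
    ]
    if items:
        _save(plot_transfer_fits(items), "transfer_functions")
    if report.fit_table.get("expression") is not None and report.fit_table["expression"].notna().any():
        _save(plot_params_vs_expression(report.fit_table), "params_vs_expression")
    return written
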