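# utakit

Single-cell analysis of miRNA-mediated gene repression with the molecular
titration model, for dual-fluorescence reporter assays read on a flow
cytometer: one fluorophore carries a perfectly complementary miRNA target
site in its 3′UTR (the reporter), the other serves as a per-cell expression
reference. Because transfection delivers a broad, roughly lognormal range of
plasmid doses, a single sample traces out a full dose–response — and its
shape tells apart miRNAs that are merely *expressed* from miRNAs that
actually *repress*.

## The model

Free target mRNA $r$ at steady state solves
$r^2 + r(\lambda + \theta - r_0) - \lambda r_0 = 0$:

$$r = \tfrac12\Bigl[(r_0 - \theta - \lambda) + \sqrt{(r_0 - \theta - \lambda)^2 + 4\lambda r_0}\Bigr]$$

where $r_0$ is the unrepressed expression level (proxied by the reference
channel), $\theta$ the effective miRNA abundance and $\lambda$ the effective
dissociation constant ($1/\lambda$ = binding capability). For a perfectly
binding small RNA ($\lambda = 0$) this is the threshold-linear law
$r = \max(r_0 - \theta, 0)$: silence below the titration point $\theta$,
stoichiometric escape above it. $\theta$ shifts the threshold, $1/\lambda$
sharpens it.

The package provides:

* `titration` — the model, its kinetic-to-effective parameter reduction, and
  dose–response / parameter-grid simulation;
* `cytometry` — a synthetic event-table generator with lognormal transfection,
  measurement noise and autofluorescence, plus copy-number and
  siRNA-competition effective-parameter helpers;
* `transfer` — gating and the binned transfer function (0.05-decade bins of
  log reference intensity vs mean log reporter intensity);
* `fitting` — `TransferFunctionModel.fit()` → `TransferFitResults`:
  weighted nonlinear least-squares estimation of $(\theta, \lambda)$ with an
  optional measurement-noise-aware mean model;
* `classify` — the low / mid / high functional categories from curve shape;
* `profiles` — median-of-ratios size factors, log2 quartile ranking,
  RPM/RPKM, compartment ratios, Kruskal–Wallis + Dunn group comparison;
* `pipeline` / `uta` CLI — the reproducible end-to-end workflow.

## Worked example

Simulate one sample (50 000 cells, true θ = 100, λ = 10 intensity units, the
default transfection/noise model), build its transfer function, and fit:

```python
from utakit import (SimulationConfig, simulate_events, gate_ref_positive,
                    compute_transfer_function, fit_transfer_function,
                    MeasurementNoise)

cfg = SimulationConfig(seed=1, theta=100.0, lam=10.0)
events = simulate_events(cfg)
gated = gate_ref_positive(events, gate=100.0)
tf = compute_transfer_function(gated, af_mean=cfg.af_mean)
fit = fit_transfer_function(tf, weights="ivar",
                            noise=MeasurementNoise.from_simulation(cfg))
print(fit.summary())
call = fit.classify()
print(f"theta_hat = {fit.theta * tf.gate_value:.1f}  "
      f"lam_hat = {fit.lam * tf.gate_value:.2f}")
print(f"category  = {call.category}")
```

prints

```
Transfer-function titration fit
==============================================
bins used                    36
gate value                  100
weighted RSS              49.55
converged                  True
----------------------------------------------
theta (abundance)         1.008  se 0.0133
lambda (dissociation)   0.09973  se 0.00459
gain (rep/ref)           0.9533  se 0.00579
theta_hat = 100.8  lam_hat = 9.97
category  = mid
```

Estimates are in gate-relative units (here gate = 100, so
$\hat\theta \approx 100.8$ and $\hat\lambda \approx 9.97$ intensity units —
within 1% of the simulation truth). The `mid` call says the repression
threshold is resolved in the lower third of the observed intensity range.

The same workflow runs from the shell:

```sh
uta run pipeline.yaml -o out/       # simulate → gate → fit → classify → compare
uta simulate --theta 100 --lam 10 --r0-min 1 --r0-max 1000 -o curve.csv
```

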