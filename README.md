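# phasesync

Phase-based analysis of resting-state BOLD dynamics: instantaneous-phase
extraction, Kuramoto order-parameter synchronization and metastability
(globally and per resting-state network), confound-residualized group
statistics with FDR control, bias-corrected bootstrap mediation, and PCA
of subcortical–cortical fiber-count matrices — together with synthetic
generators that give every stage a known ground truth.

It is aimed at researchers studying large-scale cortical dynamics (e.g.
patient-vs-control resting-state fMRI cohorts) who want a tested,
scriptable implementation of the phase-synchronization toolchain without
committing to a full neuroimaging framework: inputs are plain delimited
text (one region-by-time matrix per subject, a parcel-to-network lookup,
a phenotype table), outputs are tidy CSV/JSON.

## The statistics at the core

Given regional signals s_j(t), the Hilbert transform yields the analytic
signal s_j(t) + i·H(s_j)(t), whose angle is the instantaneous phase
θ_j(t).  Coherence of a region set at time t is the Kuramoto order
parameter

    r(t) = | (1/n) Σ_j e^{i θ_j(t)} |  ∈ [0, 1],

and two numbers summarize each subject:

* **synchronization** ⟨r(t)⟩ — the temporal mean, average phase coherence;
* **metastability** SD(r(t)) — the temporal standard deviation, how much
  the system moves between integrated and segregated states.

Downstream, group contrasts are Welch t-tests on covariate-residualized
metrics with Benjamini–Hochberg FDR control; brain–behavior associations
are partial Pearson correlations; and indirect effects (e.g. group →
metastability → cognitive score) are estimated with a three-variable path
model whose a·b term gets a bias-corrected bootstrap confidence interval.
See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Simulate one "subject" at two coupling strengths and recover the metrics
from the synthetic BOLD signal:

```python
from phasesync import (OscillatorConfig, simulate_kuramoto, phases_to_bold,
                       instantaneous_phase, order_parameter, sync_metrics)

for K in (0.5, 3.0):
    phases = simulate_kuramoto(OscillatorConfig(n_oscillators=60, coupling=K, seed=1))
    bold = phases_to_bold(phases, amplitude_sd=0.1, obs_noise_sd=0.1, seed=2)
    est = sync_metrics(order_parameter(instantaneous_phase(bold)))
    true = sync_metrics(order_parameter(phases))
    print(f"K={K}: measured sync={est.synchronization:.3f} meta={est.metastability:.3f} "
          f"(ground truth {true.synchronization:.3f}/{true.metastability:.3f})")
```

prints

```
K=0.5: measured sync=0.114 meta=0.060 (ground truth 0.119/0.064)
K=3.0: measured sync=0.557 meta=0.132 (ground truth 0.590/0.108)
```

Below the synchronization transition (K = 0.5) the 60 regions are nearly
incoherent (r stays near 1/√60 ≈ 0.13); near the transition (K = 3.0)
coherence is substantially higher and fluctuates more (higher
metastability).  The Hilbert estimate from noisy BOLD tracks the
generator's ground truth closely.

The same analysis, end to end, from the shell:

```bash
phasesync simulate --out-dir demo --n-per-group 15 --n-regions 60 --seed 1
phasesync run-all \
    --timeseries-dir demo/timeseries --parcellation demo/parcellation.csv \
    --phenotype demo/phenotype.csv --no-filter \
    --covariates age,education,fd,tiv --out-dir demo/out
```

which writes per-subject metrics (`metrics.csv`), group comparisons with
FDR (`group_comparison.csv`), metric–score correlations
(`correlations.csv`), mediation results (`mediation.json`) and a manifest
that makes the run bit-for-bit reproducible.

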