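# microdcm

Canonical-microcircuit dynamic causal modelling of stimulus-evoked
responses, as a compact, tested Python pipeline:

- **`neural_dynamics`** — four-population (spiny stellate, superficial
  pyramidal, inhibitory interneuron, deep pyramidal) neural-mass model per
  source, second-order synaptic kernels, bounded logistic firing, Gaussian
  bump exogenous input, and a fixed-step delayed integrator (Heun steps
  with cubic-Hermite history interpolation; numba-accelerated with an
  equivalent pure-numpy reference path).
- **`model_space`** — the 8-source bilateral object-naming network
  (early visual cortex, angular gyrus, anterior ventral temporal cortex,
  inferior frontal gyrus) and the three competing input architectures,
  grouped into two families; condition-specific (novel/repeated)
  log-scaling modulations.
- **`observation_model`** — LFP-style linear projection of population
  voltages to per-source signals, and a pooled variance-explained fit score.
- **`inversion`** — variational-Laplace (Gauss–Newton / Levenberg–Marquardt
  ascent on free energy) posterior estimation over log-scaling parameters,
  with an analytic noise-precision update, plus the low-fit
  re-initialization pass (group-mean restart for subjects under 0.75 fit).
- **`model_selection`** — random-effects Bayesian model selection
  (variational Dirichlet), exceedance probabilities by seeded sampling with
  a closed-form Beta cross-check for two models, and size-corrected
  family-level comparison.
- **`synthetic_data`** — seeded ground-truth cohorts (older-like: dual
  visual+frontal input, repetition effects on ventral forward connections,
  slower forward conduction; younger-like: visual input with a direct
  visual→frontal feedforward edge, repetition effects on temporal gain)
  plus reaction times negatively coupled to frontal input strength.
- **`analysis_pipeline`** — end-to-end study orchestration: per-subject
  inversion of all models, refits, family then within-family model
  selection per group, parameter harvesting, repetition-effect t-tests,
  input-strength/RT correlation and group conduction-delay comparison.

## CLI

```bash
microdcm model build --id 3 --out model3.json
microdcm simulate --group older --n 15 --seed 7 --hemispheres L --out cohort_old/
microdcm invert --data cohort_old/sub-01 --model model2.json --out post.json
microdcm compare --evidence evidence.tsv --families "1:1;2:2,3"
microdcm pipeline --manifest study.yaml --out report/
```

A study manifest is YAML or JSON:

```yaml
groups:
  older: cohort_old
  younger: cohort_young
options:
  hemispheres: [L]
  max_iter: 32
  correction: bonferroni
```

## Data formats

ERP matrices are tab-separated text (first column time in ms, one column
per source, header row of source names) with a JSON metadata sidecar per
subject; evidence tables are subjects × models TSV; reports and posteriors
are JSON.
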