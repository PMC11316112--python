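# disagreesim

Simulator and analytic toolkit for disagreement between two agents who base
a binary policy recommendation on the same evidence.

Two evidence streams emit i.i.d. Gaussian observations with unknown means
and known standard deviations. Each agent learns the stream means by
conjugate Gaussian updating, combines her per-stream posterior means with a
personal weight `w` into a posterior over policy support

```
mu     = w * mean_x + (1 - w) * mean_y
sigma2 = w^2 * var_x + (1 - w)^2 * var_y
```

and recommends FOR the policy iff `mu > threshold`. Agents may also carry an
additive observation bias per stream (so their learning converges to the true
mean plus the bias), streams may emit at different rates, and reported
assessments may lag the posterior through exponential-smoothing inertia.

The package provides:

- `disagreesim.model_core` — belief updating, weighted combination,
  analytic large-sample limits;
- `disagreesim.simulation` — a seeded paired-run Monte Carlo harness
  (both agents see the same draws; common random numbers across configs)
  with published scenario fixtures;
- `disagreesim.disagreement` — classification of **support** (posterior
  means differ), **policy** (recommendations differ; entails support) and
  **uncertainty** (posterior SDs differ) disagreement, plus the analytic
  uncertainty-vs-weight curve (symmetric around 0.5; the variance at weight
  0 or 1 is twice the variance at 0.5 under equal priors);
- `disagreesim.identifiability` — whether an observed limiting belief can be
  explained without bias: any limit inside the interval spanned by the true
  stream means has a bias-free witness weight `w* = (c - mu_y)/(mu_x - mu_y)`,
  so faulty and faultless configurations are empirically indistinguishable
  there; limits outside that interval require bias;
- `disagreesim.cli_io` — YAML/JSON configs, tidy CSV run records with a JSON
  sidecar, and the `disagreesim` command-line driver.

> **Reconstruction notes.** The prior variance (default `s2 = 1`), the
> inertia mechanism (exponential smoothing, default `lambda = 0.9`) and the
> per-run observation count (default `n_steps = 10_000`) are documented
> defaults, configurable throughout; resolved values are logged at INFO.

## CLI

```bash
# list / export the published scenario fixtures
disagreesim fixtures --list
disagreesim fixtures --write configs/

# run 100 paired simulations of the two-weights scenario, tidy CSV out
disagreesim simulate --fixture fig3 --out runs.csv
disagreesim simulate --config configs/fig5_slow.yaml --n-runs 20 --out slow.csv

# analytic limiting support means and recommendations
disagreesim limits --fixture fig3

# can these observed limits be explained without bias?
disagreesim diagnose --cd 0.55 --cr 0.65 --mux 0.7 --muy 0.2 --json

# posterior support variance as a function of the stream weight
disagreesim uncertainty-curve --n 100 --out curve.csv

# quick trajectory plot from a run-record CSV
disagreesim plot --runs runs.csv --out fig.png
```

`simulate` writes one CSV row per (run, step, agent) — columns `run_id`,
`step` (observations from stream Y), `n_x`, `agent`, `support_mean`,
`support_sd`, `recommendation`, `reported_assessment`, and pair-level
disagreement flags/magnitudes — plus `<out>.meta.json` holding the fully
resolved config and package version. Re-running the same config yields
byte-identical output.

The config schema is documented in `disagreesim/cli_io.py` (module
docstring); `fixtures --write` emits ready-made examples.

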