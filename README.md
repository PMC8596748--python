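# scdetect

Simulation and automated effect detection for single-case AB graphs.

Behavior analysts and n-of-1 researchers routinely judge two-phase
(baseline A, treatment B) graphs by eye, a practice with well-documented
reliability problems. `scdetect` provides the computational side of that
debate: a Monte Carlo simulator of AB graphs with controlled phase lengths,
autocorrelation, trend, variability and effect size, plus three automated
detectors — the conservative dual-criteria (CDC) visual aid, a hinge-loss
stochastic-gradient linear classifier (SGD), and an RBF support vector
classifier (SVC) — and an evaluation harness measuring accuracy, Type I
error rate, power, and pairwise agreement, stratified by graph
characteristic. Human ratings (one 0/1 judgment per graph) can be dropped
into the same agreement analysis.

## The model

Each simulated series of length `n_a + n_b` is built as

1. **AR(1) noise** — `x_t = a·x_{t−1} + e_t`, `e_t ~ N(0, 1)`, `x_1 = e_1`,
   with `a ∈ {0, 0.2}`;
2. **trend** — a shear about the series midpoint adding
   `tan(θ)·(i − m)` to session `i` (`θ ∈ {0°, 30°}`; at 30° consecutive
   points change by ≈ 0.58);
3. **level** — a constant (+10 "stable", +4 "variable") setting the
   variability coefficient SD/mean to 0.10 or 0.25;
4. **effect** — a standardized mean difference `SMD ∈ {0, …, 5}` added to
   every Phase B point.

The **CDC rule** projects the baseline mean and baseline OLS trend line over
Phase B, raises both by 0.25 baseline SD, and declares an effect when at
least 5 of 5 (or 8 of 10) treatment points exceed both lines.

The **classifiers** see 8 features per graph, computed after standardizing
the series to mean 0 / SD 1: per-phase mean, SD, OLS intercept and slope.
They are trained on a 96,000-graph counterbalanced set (half no-effect) and
evaluated on an independent 1,024-graph set (12 no-effect + 4 × 5 effect
graphs for each of the 32 combinations of the binary characteristics).

Every proportion carries a Wald 95% binomial interval
`p ± 1.96·√(p(1−p)/n)`.

## Worked example

```python
from scdetect import generate_test_dataset, cdc_batch, evaluate_method

graphs = generate_test_dataset(seed=7)      # 1,024 counterbalanced AB graphs
decisions = cdc_batch(graphs)               # CDC verdict per graph, 0/1
report = evaluate_method("cdc", decisions, graphs.labels, graphs)
```

prints, via `report`:

```
accuracy   0.739  (95% CI 0.712-0.766)
type I     0.190  on 384 no-effect graphs
power      0.697  on 640 effect graphs
type I | no trend 0.052   type I | 30 deg 0.328
power by SMD: 1:0.34  2:0.60  3:0.74  4:0.88  5:0.91
```

The CDC rule is well calibrated on trend-free graphs (Type I ≈ .05) but its
false-alarm rate jumps to ≈ .33 when a 30° trend is present, and power
climbs steeply with effect size — the trade-offs the harness is built to
expose.

The same pipeline is scriptable from a shell:

```bash
scdetect simulate --scheme test_1024 --seed 7 --out data/
scdetect apply-cdc --manifest data/manifest.csv --out cdc_values.csv
scdetect train --model sgd --seed 1 --out sgd.joblib
scdetect predict --model-file sgd.joblib --manifest data/manifest.csv --out sgd_values.csv
scdetect evaluate --truth data/true_values.csv \
    --pred cdc=cdc_values.csv --pred sgd=sgd_values.csv \
    --manifest data/manifest.csv --out report
scdetect render --manifest data/manifest.csv --out graphs.pdf
```

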