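# seagrass-metals

Bayesian analysis of trace-metal dynamics (Cu, Zn, Cd, Pb) during eelgrass
(*Zostera marina*) leaf decomposition, for researchers studying metal
cycling in seagrass ecosystems. Shed seagrass leaves decompose on the
sediment surface; whether a metal concentrates in the decaying tissue or
leaches out of it decides whether seagrass beds act as a metal sink. The
package implements the full inference chain over mesocosm-style data and a
synthetic-data generator with known ground truth, so every estimator can be
validated by parameter recovery.

The chain has four parts:

1. **Epiphyte weight ratio (WRE)** — the mass fraction r of epiphytes on
   initial leaves, inferred from elemental tracers (C, δ13C, optionally N,
   δ15N) by a two-source Bayesian mixing model with source variability:
   x_t ~ N((1−r)μ_eel + rμ_epi, (1−r)²σ²_eel + r²σ²_epi), uniform prior,
   random-walk MCMC (200,000 iterations, 50,000 burn-in, thin 15).
2. **Decomposition model** — per metal × experiment,
   log_e y = β1 + β2·C + ε, ε ~ N(0, σ²), with C the leaf carbon content;
   conjugate normal–inverse-gamma priors, Gibbs sampling with 3 chains
   (5,000 burn-in + 50,000 kept each, thinned to 10,000 pooled draws), and
   detection-limit substitution for censored values.
3. **Posterior-predictive fold-changes** — concentrations predicted at the
   initial-leaf carbon content C(0) = (1−r)C_eelgrass + rC_epiphytes and at
   the lowest observed C, integrating over the WRE posterior, source-carbon
   uncertainty, the regression posterior and observation noise (100,000
   Monte-Carlo iterations); the ratio of the two is the decomposition
   fold-change.
4. **Sediment statistics** — geometric annual summaries, Kruskal–Wallis
   tests across sediment groups, Dwass–Steel–Critchlow–Fligner all-pairs
   comparisons with a Monte-Carlo max-statistic familywise null, and
   log-linear element-vs-δ13C trend fits per pool.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the chain end to end on a
synthetic dataset (seed 1, defaults mirroring the mesocosm study design)
and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_fit_wre.py
python analysis/03_fit_decomposition.py
python analysis/04_predict_fold_changes.py
python analysis/05_sediment_stats.py
```

`02_fit_wre.py` prints, for the two tracer combinations:

```
WRE (c_content+d13c): 0.232 +/- 0.019, 95% CI 0.195-0.270  (truth 0.192)
WRE (c_content+d13c+n_content+d15n): 0.255 +/- 0.019, 95% CI 0.219-0.293  (truth 0.192)
```

— the posterior mean ± SD and equal-tailed 95 % credible interval of the
epiphyte mass fraction, to be compared with the generative truth 0.192.
`03_fit_decomposition.py` fits all 12 metal × experiment pairs, e.g.

```
cu EX1: beta2 -0.118 [-0.134, -0.102] truth -0.120 ok
pb EX2: beta2 -0.275 [-0.294, -0.256] truth -0.277 ok
...
11/12 slope truths inside their 95% CI
```

where β2 is the change in log_e concentration per % carbon (negative:
the metal concentrates as the leaf decomposes). `04_predict_fold_changes.py`
then reports, per metal × experiment, the predicted concentration at C(0)
and at the lowest observed carbon content and their ratio:

```
cu EX2:     1.99 ->     13.5 ug/g  fold   6.77 (up)
zn EX2:      334 ->     68.4 ug/g  fold   0.20 (down)
```

— copper and lead concentrate during decomposition, zinc and cadmium
deplete. `05_sediment_stats.py` closes with the sediment contrast: metals
trend significantly with δ13C in the vegetated pool's surface sediment but
not in the reference pool.

The same functionality is available as a CLI
(`seagrass-metals simulate|fit-wre|fit-decomp|predict|sediment-trends|compare-groups|run-all`)
and, of course, as the library under `src/seagrass_metals`.

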