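# vwmmix

Hierarchical Bayesian mixture measurement models for continuous-reproduction
(delayed-estimation) visual working memory tasks, in pure scientific Python.

Five model variants share one estimation pipeline:

| model | parameters (link) | idea |
|---|---|---|
| `mixture2p` | `kappa` (log), `thetat` | target von Mises + uniform guessing |
| `mixture3p` | + `thetant` | + non-target (swap) components |
| `imm_abc` | `kappa`, `c`, `a` (log) | activations: context, general, background b = 1 |
| `imm_bsc` | `kappa`, `c`, `s` (log) | distance-dependent generalization gradient |
| `imm_full` | `kappa`, `c`, `a`, `s` (log) | both |

Mixing weights are mapped to probabilities with a softmax whose guessing
weight is fixed at 0; the guessing kernel is a von Mises with
log kappa = −100 (numerically uniform). Each model parameter gets its own
mixed-model formula (`0 +` cell-means coding, `a:b` interactions,
`(terms || group)` uncorrelated random effects, `(terms | gr(id, by = g))`
stratified, correlated random effects), with treatment, cell-means, or
successive-difference contrasts — the latter combined with lower-bounded
priors yields monotonicity constraints across conditions.

Estimation is Hamiltonian Monte Carlo over the full hierarchical posterior
(analytic gradients, non-centered random effects, diagonal mass-matrix and
step-size adaptation, divergence counting). Diagnostics (split R-hat, ESS)
come from arviz. Post-processing covers link→native transforms
(exp / softmax / kappa→circular SD→degrees), posterior predictive density
overlays, and Savage–Dickey / directional hypothesis tests.

## Python API

```python
import vwmmix as v

model = v.make_model("mixture3p",
                     response_col="response_error",
                     nt_cols=v.standard_nt_columns(6),   # col_lure1..col_lure5
                     set_size_col="setsize")

fit = v.fit(model,
            ["kappa  ~ 0 + setsize + (0 + setsize || subID)",
             "thetat ~ 0 + setsize + (0 + setsize || subID)",
             "thetant ~ 0 + setsize + (0 + setsize || subID)"],
            table, factors=["setsize"], chains=4, warmup=1000, iter=1000,
            seed=123, sample_prior=True)

v.summarize(fit)                      # two-section summary (link scale)
v.to_native(fit.flat("kappa_setsize2"), "kappa")          # exp
v.to_native(fit.flat("thetat_setsize2"), "theta-set")     # softmax
ppc = v.pp_check(fit, n_draws=10, seed=1)
v.hypothesis(fit, {"cue": "thetat_setsize1 - thetat_setsize2 > 0"})
```

Data are long format, one row per retrieval, all angles in radians wrapped
to (−π, π]; non-target features are coded relative to the target
(`recode_relative`), inactive slots empty (zeros beyond `set_size − 1` are
normalized to missing on load). `validate_table` flags schema problems and
likely degrees-coded columns. `simulate_trials(GenerativeConfig(...))`
generates data with known truth (and latent component labels) for recovery
studies; priors are inspectable via `default_priors` and overridable with
`prior("normal(0, 1)", parameter="kappa", coef="setsize2", lb=0)`.

## CLI

```bash
vwmmix simulate  --config config.json --out trials.csv
vwmmix fit       --model mixture2p \
                 --formula "kappa ~ 0 + setsize + (0 + setsize || subID)" \
                 --formula "thetat ~ 0 + setsize + (0 + setsize || subID)" \
                 --data trials.csv --factors setsize \
                 --chains 4 --warmup 1000 --iter 1000 --seed 1 --out fit/
vwmmix summarize --fit fit/ --native
vwmmix ppcheck   --fit fit/ --draws 10 --seed 1 --out ppc.csv
vwmmix hypothesis --fit fit/ --statements hyp.json
```

`fit/` holds tidy-CSV draws (`chain, iteration, coefficient, value`),
convergence diagnostics, the prior table, and run metadata as JSON.

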