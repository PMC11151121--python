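# coophaz — cooperative polygenic hazard score models

`coophaz` fits Cox proportional-hazards models whose coefficients are
learned **jointly across several data layers** (for example an
epidemiological table, selected genomic loci, and methylation levels for
the same cohort), producing per-individual hazard and survival curves for
a right-censored outcome such as age of disease onset.  It is aimed at
biostatisticians who want an interpretable multi-omic survival model: a
linear score per layer, a weighting of the layers' predictive
contributions, and absolute time-dependent risk rather than a single
point estimate.

## The model

For individual *i* with covariate rows `z_1,…,z_m` (one per layer) the
hazard is

    h(t | z_1,…,z_m) = h_0(t) · exp( Σ_j β_jᵀ z_j )

with a nonparametric baseline `h_0`.  The per-layer coefficients are
fitted in two steps.  First each layer's unpenalized Cox partial
log-likelihood `l_{Z_j}(β)` is maximized, giving preliminary estimates
`β̂_j`.  Then all layers are fitted jointly by minimizing

    −(1/n) Σ_j l_{Z_j}(β_j)
    + (ρ/2) Σ_{i<j} ‖Z_i β_i − Z_j β_j‖²
    + λ Σ_j Σ_k |β_{j,k} / β̂_{j,k}|

The quadratic **agreement penalty** (weight ρ) forces the layer-wise
linear predictors to agree — ρ = 0 is late fusion (independent fits),
large ρ trades likelihood for consistency.  The adaptive-lasso term
(weight λ, componentwise division by the preliminary estimates) induces
sparsity; λ can be selected by cross-validated integrated Brier score.
After fitting, each `β_j` is rescaled to unit Euclidean norm, the
Breslow baseline cumulative hazard is estimated on the combined linear
predictor, and survival follows as `S(t) = exp(−∫₀ᵗ h)`.

Comparators (early fusion on the concatenated layers, a
conditional-partial-likelihood model, the ρ = 0 late-fusion variant),
the four evaluation metrics (normalized L1 loss, AUC, Harrell's
concordance index, IPCW integrated Brier score), and two synthetic
cohort generators (a Balding–Nichols genotype + coupled-methylation
simulator, and a within-group entry-wise bootstrap with optional age
separation) are included, so the whole pipeline runs without external
data.

## Worked example

```python
import coophaz as ch

cfg = ch.SimulationConfig(n=100, n_g=20, n_m=20, n_p=8, seed=1)
cohort = ch.generate_cohort(cfg)
layers = [cohort.genetic, cohort.methylation]

opts = ch.FitOptions(on_nonconvergence="warn", allow_constant=True)
model = ch.fit_cooperative(
    layers, cohort.outcome,
    ch.CoopConfig(rho=1.0, lam=0.01, fit_options=opts))

print("layer weights:", ch.layer_weights(model, layers))
ind = ch.predict_curves(model, layers)[0]
for age in (60, 70, 80, 90):
    print(f"S({age}) = {ind.survival_at(age):.3f}")
```

Output:

```
layer weights: [0.233 0.767]
S(60) = 0.916
S(70) = 0.773
S(80) = 0.421
S(90) = 0.277
```

The cohort has 49 cases among 100 individuals.  The layer weights say
that about 77% of the fitted linear-predictor variation comes from the
methylation layer; the printed values are the first individual's
predicted probability of remaining event-free past each age, decreasing
from 0.92 at age 60 to 0.28 at age 90.

The same pipeline is available from the shell:

```sh
coophaz simulate --n 100 --ng 20 --nm 20 --np 8 --seed 1 --out-prefix sim
coophaz fit --layer sim_genetic.csv --layer sim_methylation.csv \
            --outcome sim_outcome.tsv --lam 0.01 --out model.json
coophaz predict --model model.json --layer sim_genetic.csv \
                --layer sim_methylation.csv --out curves.csv
coophaz evaluate --curves curves.csv --outcome sim_outcome.tsv \
                 --out metrics.json
```

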