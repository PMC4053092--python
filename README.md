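# rapsig

Drug-response gene-expression signatures, from training to in-vivo
validation, as a tested and reproducible Python pipeline.

`rapsig` is for computational biologists who want to build a
treated-versus-control **drug response signature** from a small cell-line
training set, validate it, and apply it to tumor cohorts — the workflow
behind questions like "which breast-cancer subtypes should respond to an
mTOR inhibitor?".  It also implements the two companion analyses such a
study needs: EC50 estimation from dose-response viability screens, and
percent tumor-growth inhibition (TGI) from xenograft caliper data.  A
synthetic-data module generates every input class with known ground
truth, so the whole pipeline runs and is validated without any external
download.

## The model

Training profiles (probes × samples, linear intensities) are quantile
normalized and log2 transformed.  Probes are ranked by the absolute
pooled-variance two-sample t-statistic between treated and control; the
top k = 200 probes form the signature.  Their submatrix is row-centered
and decomposed by SVD, giving unit-norm probe weights **w** (the first
principal component) and a scalar **metagene score** s_j = **w**ᵀx_j per
sample.  A Bayesian probit regression

    P(treated_j) = Φ(β₀ + β₁ s_j),   β ~ N(0, 10² I)

is fitted by the Albert–Chib Gibbs sampler, and predictions average
Φ(β₀ + β₁ s) over the posterior draws.  A new sample is standardized
against the signature's frozen reference quantiles and training
statistics, projected onto **w**, and assigned

    sensitivity = 1 − P(treated)

— samples resembling *untreated* cells (pathway still active) are called
**sensitive** (> 0.5), treated-like samples **resistant**.  Internal
validation is leave-one-out cross-validation with probe re-selection
inside every fold.

Dose-response curves use the constrained sigmoid
v(d) = bottom + (top − bottom)/(1 + d/EC50) (Hill slope 1) fitted on log
viability; predicted sensitivity is compared with log10 EC50 by linear
regression.  Xenograft volumes are V = l·w²/2 from caliper pairs, and
TGI = 100 × (1 − ΔV_treated/ΔV_control) at the last common day, with
pooled-variance Student's t-tests on final volumes.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and limitations.

## Worked example

Everything is scriptable from Python (`import rapsig`), but the quickest
tour is the CLI demo, which simulates a study, builds and cross-validates
a signature, scores a subtype-annotated cohort, fits a dose-response
panel, and analyzes a xenograft trial:

```sh
rapsig demo --seed 5 --n-probes 2000 --cohort-scale 0.05 --out demo/
```

prints (abridged):

```
## Signature
- 200 probes; 164 of 200 planted probes recovered
- LOOCV: 22 of 23 samples correctly classified

## Subtype sensitivity summary
            subtype  n_samples  n_sensitive  percent_sensitive
HER2-overexpressing          9            2          22.222222
         basal-like         13           11          84.615385
          luminal A         22            2           9.090909
          luminal B         14            3          21.428571
        normal-like         12            1           8.333333

## EC50 vs predicted sensitivity
- slope -0.344 (log10 M per unit sensitivity), r = -0.118, p = 0.6405

## Xenograft efficacy
- rapamycin arm tumor-growth inhibition: 95.0%
```

Reading the output: the signature recovered 164 of the 200 probes the
generator actually planted and classified 22 of the 23 training samples
correctly under leave-one-out cross-validation.  On the synthetic cohort,
basal-like tumors — generated with the highest pathway activation — show
the highest fraction predicted sensitive.  The negative regression slope
says higher predicted sensitivity goes with lower EC50 (more potent
inhibition), and the simulated trial, programmed with 94% growth
suppression, is recovered at 95% inhibition.

The same stages are available as composable subcommands (`simulate`,
`build-signature`, `loocv`, `predict`, `subtype-report`, `ec50`,
`correlate`, `tgi`), each accepting a YAML config via `--config`,
echoing its resolved options into the output directory, and appending a
JSON-lines run log.

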