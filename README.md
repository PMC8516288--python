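# mitowave

Inference toolkit for transcription reactivation dynamics as cells exit
mitosis, with a self-consistent synthetic-data generator for end-to-end
validation.

## The problem

When a population of cells is released from a mitotic block, transcription —
globally silenced during mitosis — switches back on in waves. Bulk
measurements taken *t* minutes after release are hard to interpret directly,
because each sample mixes cells at different stages of exit: every cell waits
a random lag η before its own division, and the culture is further
contaminated by permanently arrested and never-blocked interphase cells.

`mitowave` implements the full chain of models needed to turn such data into
per-gene reactivation profiles and per-motif regulator activities:

1. **Lag model** (`mitowave.lag`). The lag is log-normal,
   η ~ LogNormal(μ, σ), and mitosis itself lasts τ_mit minutes. The fraction
   of cells still mitotic at time *t* is
   q(t) = ½ − ½·erf((log(t − τ_mit) − μ) / (√2·σ)) for t > τ_mit (and 1
   before). Fitting q(t) to binomial mitotic/total counts by maximum
   likelihood recovers (τ_mit, μ, σ), with parametric-bootstrap
   uncertainties.
2. **Deconvolution** (`mitowave.deconvolution`). Each observed bulk profile
   is a known mixture of pseudotime states,
   r_g(t) = π_C ∫ E_g(τ) P(τ | t) dτ + π_M E_g(0) + π_I E_g^I,
   where pseudotime τ = t − η is the time since a cell's own division.
   Written as r = M·E this is inverted in closed form with a first-difference
   smoothness penalty; the penalty weight is selected by BIC using the
   effective degrees of freedom Tr(M(MᵀM + λK)⁻¹Mᵀ).
3. **Preprocessing** (`mitowave.preprocess`): transcript-to-gene aggregation
   with an expression filter, row z-scoring, adaptive-pseudocount log2
   normalization, and peak-ordered k-means clustering of profiles.
4. **Motif activities** (`mitowave.activity`): ridge regression of log
   expression on promoter site counts, e_gτ = Σ_f N_gf A_fτ, with the penalty
   chosen by cross-validation over genes, plus classification of activity
   waves as mitotic- or early-G1-active and activity–expression
   cross-correlation.
5. **Regulatory network** (`mitowave.regnet`): leave-one-motif-out importance
   ranking, extraction of the core regulatory network among top motifs with a
   random-draw baseline, mitotic bookmarking scores (site-weighted mean of
   per-TF mitotic binding fractions), mitotic activity scores, peak-to-gene
   assignment and group expression contrasts.
6. **Synthetic data** (`mitowave.simulate`): a seeded generator producing
   mitotic counts, site matrices, wave-shaped activities, expression and
   bulk observations through the exact forward mixture — ground truth for
   every stage above.

## Worked example

```python
import numpy as np
from mitowave import (SimulationConfig, simulate_mitotic_counts, fit_lag_model,
                      simulate_expression_and_observe, zscore_rows,
                      select_lambda, deconvolve, unzscore_rows)

# recover the lag parameters from a 200-cell counting experiment
counts = simulate_mitotic_counts(SimulationConfig(seed=0))
p = fit_lag_model(counts).params
print(p.tau_mit, p.mu, p.sigma)   # 68.7, 3.33, 0.77  (truth: 67, 3.4, 0.7)
print(round(p.median_lag))        # 28 min median lag after release

# deconvolve a noise-free time course at the BIC-selected penalty
truth = simulate_expression_and_observe(
    SimulationConfig(seed=5, n_genes=200, n_tfs=15, noise_sd=0.0))
z, mu, sigma = zscore_rows(truth.observed_expression)
_, lam = select_lambda(z, truth.design, np.logspace(-3, 3, 13))
E = unzscore_rows(deconvolve(z, truth.design, lam).grid_part, mu, sigma)
# mean per-gene correlation with the true pseudotime profiles: 0.938
```

The `examples/` directory walks through each stage as a short narrative
script: `fit_lag_model.py`, `deconvolve_time_course.py`,
`infer_tf_activities.py` (recovered activities correlate 0.95 with the
planted truth) and `core_network_and_bookmarking.py`.

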