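"""Rank motifs, extract the core regulatory network and score bookmarking.

Leave-one-motif-out refits rank motifs by how much explained variance they
carry; the top 5% form a core whose mutual promoter connections are compared
to a random-draw baseline. Promoter-level mitotic binding scores summarize
how strongly each gene is bookmarked through mitosis.
"""

import numpy as np
import pandas as pd

from mitowave import (
    SimulationConfig,
    build_crn,
    group_expression_contrast,
    importance_scores,
    mitotic_binding_score,
    random_network_baseline,
    select_core,
    simulate_expression_and_observe,
)

config = SimulationConfig(seed=13, n_genes=200, n_tfs=20, noise_sd=0.05)
truth = simulate_expression_and_observe(config)
sites = truth.true_site_matrix
e = truth.true_log_expression

ranking = importance_scores(e, sites, lam=1.0)
core = select_core(ranking, fraction=0.25)
print(f"top motifs by importance (lower score = larger EV drop when removed):")
print(ranking.table.head(5).to_string(float_format=lambda v: f"{v:.3f}"))

motif_to_gene = {m: tfs[0] for m, tfs in sites.motif_to_tfs.items()}
crn = build_crn(core, sites, motif_to_gene)
mean, sd = random_network_baseline(sites, motif_to_gene, len(core), n_draws=500, seed=0)
print(f"\ncore of {len(core)} motifs: {crn.edge_count} promoter-binding edges "
      f"(random cores of the same size: {mean:.1f} +/- {sd:.1f})")

# synthetic bookmarking fractions: motifs peaking early bind mitotic chromatin
peaks = truth.true_activities.peak_time
mbf = pd.Series(np.where(peaks < config.true_lag.tau_mit, 0.8, 0.2),
                index=peaks.index)
scores = mitotic_binding_score(sites, mbf)
groups = {g: scores.index[scores["group"] == g].tolist() for g in ("high", "low")}
contrast = group_expression_contrast(truth.true_expression, groups)
argmax = {g: contrast[g].loc["mean"].to_numpy().argmax() for g in groups}
print(f"\nmean expression of the top bookmarking decile peaks at "
      f"{argmax['high']} min vs {argmax['low']} min for the bottom decile:")
print("promoters bound through mitosis reactivate earlier after division.")
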