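"""Velocity direction corruption by MURK genes, and its rescue by removal.

Simulates genes being induced from zero along the trajectory with a MURK-heavy
panel (the erythroid regime), fits the steady-state velocity model, and scores
how well the velocity field agrees with the true latent time: positive means
the inferred arrows point forward in real time.  The step-change genes steepen
their fitted steady-state lines, flipping mid-trajectory velocities negative;
dropping the detector-flagged genes restores the forward signal.
"""

import numpy as np

from murkscreen import detect_murk, direction_score, fit_velocity, preprocess, simulate_dataset
from murkscreen.simulate import rescue_demo_config

cfg = rescue_demo_config(seed=7)
layers, cells, _ = simulate_dataset(cfg)
imputed, graph = preprocess(layers)

decisions = detect_murk(imputed, cells, early_pop="Ery2", late_pop="Ery3")
murk_ids = set(decisions.loc[decisions.is_murk, "gene_id"])

vfit = fit_velocity(imputed)
t = cells["latent_time"].to_numpy()
score_all = direction_score(vfit.velocity, imputed.S, t, graph, gene_mask=vfit.retained)
keep = vfit.retained & ~np.asarray(imputed.gene_ids.isin(murk_ids))
score_removed = direction_score(vfit.velocity, imputed.S, t, graph, gene_mask=keep)

print(f"genes flagged by the screen      : {len(murk_ids)} of {imputed.n_genes}")
print(f"direction score, all genes       : {score_all:+.4f}")
print(f"direction score, flagged removed : {score_removed:+.4f}")
print(
    "\nBoth scores are positive here, but removing the step-change genes"
    "\nconsistently raises the agreement with true latent time - the in-silico"
    "\nversion of cleaning reversed velocity arrows on an erythroid branch."
)
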