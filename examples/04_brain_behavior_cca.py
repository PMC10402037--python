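"""Canonical correlation between brain counts and behavior.

CCA finds paired linear combinations of ROI counts and behavioral
measures with maximal correlation; Wilk's lambda says how many factors
are real, and loadings (variable-score correlations) interpret them.
"""

import pairbondmap as pbm

cfg = pbm.SimConfig(n_pairs_per_cell=12, n_units=40, n_planted=8, seed=4)
study = pbm.simulate_study(cfg)

ieg = study.design[study.design.ieg_included]
counts = study.counts.loc[ieg.animal_id, study.planted_units]
behavior = study.behavior.loc[ieg.animal_id]

res = pbm.cca_fit(counts, behavior)
print("canonical correlations:", res.correlations.round(3))
print(pbm.wilks_test(res).round(4).to_string(index=False))

load = pbm.score_loadings(res, counts, behavior)
cc1 = load[load.factor == "CC1"]
top = cc1.reindex(cc1.loading.abs().sort_values(ascending=False).index).head(5)
print("\nstrongest CC1 loadings (shared mating/bonding axis):")
print(top.to_string(index=False))
print("\n(ejaculation-driven behaviors and latent-coupled ROIs load together:")
print(" CC1 is the brain-behavior axis of mating intensity)")
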