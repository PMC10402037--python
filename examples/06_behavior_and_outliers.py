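"""Behavioral group comparisons and the whole-brain count QC screen.

Welch t-tests compare mates with sibling controls (dyadic measures at
pair level), paired t-tests compare female and male mates, all
FDR-corrected at q < 0.05; a generalized ESD (Rosner) test screens
per-animal whole-brain count totals for outliers.
"""

import numpy as np

import pairbondmap as pbm

cfg = pbm.SimConfig(n_pairs_per_cell=12, n_units=60, n_planted=10, seed=6)
study = pbm.simulate_study(cfg)

tests = pbm.batch_tests(study.behavior, study.design, alpha=0.05)
overall = tests[tests.timepoint.isna() & (tests.kind == "welch")]
print("mate vs sibling (all timepoints pooled):")
print(overall[["measure", "n1", "n2", "t", "df", "p", "q", "significant"]].round(4).to_string(index=False))
print("\n(mating measures separate the groups; locomotion does not -- the")
print(" dyadic rows use one observation per pair, hence the smaller n)")

totals = study.counts[study.atlas.leaves()].sum(axis=1).astype(float)
totals.iloc[0] *= 4  # plant one aberrant brain
report = pbm.rosner_esd(totals, max_outliers=5, alpha=0.05)
print(f"\nESD outlier screen: {report.flagged.sum()} flagged")
print(report.round(3).to_string(index=False))
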