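"""Ordinal PCA of candidate genotypes and passage-date association.

Simulates the chronotype scenario: one panmictic source population whose
migrants carry a shared early/late liability expressed at four candidate
loci.  Fits the optimal-scaling PCA over breeding + migrant genotypes,
regresses capture day on PC1 with a sex covariate, and tests the weekly
allele-frequency trajectory of the top locus for nonlinearity with a
likelihood ratio test.
"""

import numpy as np
import pandas as pd

import chronoscan as cs

ds = cs.simulate_scenario("chronotype", seed=1)

# optimal-scaling PCA of the candidate loci, breeding + migrants jointly
cand = ds.timing_loci
joint = cs.GenotypeMatrix(
    list(ds.baseline_gm.sample_ids) + list(ds.migrant_gm.sample_ids),
    cand,
    np.vstack([ds.baseline_gm.subset_loci(cand).codes, ds.migrant_gm.subset_loci(cand).codes]),
    ["A"] * len(cand),
)
pca = cs.fix_sign(cs.fit_ordinal_pca(joint, cs.PcaConfig(n_dim=2)))
print(f"PC1 explains {pca.vaf_percent[0]:.1f}% of the candidate-gene variation, "
      f"PC2 {pca.vaf_percent[1]:.1f}% ({pca.n_iter} ALS iterations)")

# does multilocus genetic variation predict passage date?
scores = pd.Series(pca.object_scores[:, 0], index=pca.sample_ids)
fit = cs.fit_pc_timing(scores, ds.migrant_meta, terms=("pc", "sex"))
print(f"capture_day ~ PC1 + sex: PC1 p = {fit.pvalues['pc']:.2e}, "
      f"R^2 = {fit.r_squared:.2f}; sex p = {fit.pvalues['sex']:.2f}")

# weekly major-allele trajectory of the strongest locus, linear vs curved
gmr = cs.repolarize_major(ds.migrant_gm, list(ds.migrant_gm.sample_ids))
wf = cs.weekly_frequencies(gmr, ds.migrant_meta, cand[0])
red, full, lrt = cs.fit_trend_lrt(wf, degree_full=2)
print(f"\nweekly frequencies at {cand[0]} ({len(wf)} weeks):")
print(wf[["midpoint_day", "n_individuals", "frequency"]].round(2).to_string(index=False))
print(f"linear slope p = {red.pvalues['day^1']:.2e}; "
      f"curved-vs-linear LRT = {lrt.statistic:.2f}, p = {lrt.p_value:.3f}")
print()
print("PC1 summarises the correlated candidate loci (the chronotype axis) and")
print("strongly predicts passage date, while sex does not; the major-allele")
print("frequency declines across the season as early chronotypes pass first.")
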