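"""Error rate vs feature-subsampling fraction, with comparison arms.

A scaled version of the headline experiment: a handful of informative
covariates hidden among noise genotypes.  The subspace forest's OOB error is
swept over feature fractions and compared with the classical per-node-sqrt(m)
forest and plain bagging.
"""

import cureforest as cf

cohort = cf.generate_pbc_like(n=250, seed=3, n_noise=1000)
print(f"Cohort: {cohort.n} subjects, {cohort.n_variables} variables "
      f"(17 informative, 1000 noise genotypes)")

config = cf.ForestConfig(n_trees=60, criterion="logrank", seed=11)
result = cf.run_subsample_sweep(cohort, fractions=[0.05, 0.25, 0.75],
                                config=config, include_classical=True,
                                include_bagging=True)
print("\n  method     fraction   OOB error")
for _, row in result.records.iterrows():
    frac = "   -  " if row["method"] == "classical" else f"{row['fraction']:6.2f}"
    print(f"  {row['method']:<10} {frac}     {row['oob_error']:.3f}")
print("\nWide per-tree subspaces keep the rare informative variables in play;")
print("the classical per-node draw of sqrt(m) candidates almost never sees")
print("them, which drives its error toward 0.5 (random guessing).")
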