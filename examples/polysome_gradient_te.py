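"""Polysome-gradient qRT-PCR estimate of per-mRNA TE.

An HKR1-like mRNA needs the deleted factor only when the treatment has
impaired initiation: its TE falls ~2.5-fold under treatment in the
mutant, but only ~1.25-fold in WT.  The forward model emits A260 areas,
18S levels, fraction volumes and Ct values; the estimator inverts the
whole normalisation chain and summarises treated/untreated TE ratios
as mean +/- SEM with a Welch t-test between genotypes.
"""

import ribotekit as rk

CONDS = [(g, t) for g in ("WT", "mutant") for t in ("untreated", "treated")]
te_truth = {
    "HKR1like": {("WT", "untreated"): 3.0, ("WT", "treated"): 2.4,
                 ("mutant", "untreated"): 3.0, ("mutant", "treated"): 1.2},
    "ACT1like": {c: 4.0 for c in CONDS},
}

cfg = rk.GradientSimConfig(seed=3, n_replicates=3, level_noise=0.05)
gradients = rk.simulate_gradient(te_truth, cfg)
table = rk.estimate_te_table(gradients)
delta = rk.delta_te_with_sem(table, "HKR1like")

f = gradients[0].fractions
mono = float(f.loc[f["multiplier"] == 1, "a260_area"].sum())
poly = float(f.loc[f["multiplier"] >= 2, "a260_area"].sum())

print(f"P/M ratio, first gradient: {rk.pm_ratio(mono, poly):.2f}")
print("treated/untreated TE ratio for the HKR1-like mRNA:")
for genotype, row in delta.iterrows():
    print(f"  {genotype:>7}: {row['mean_ratio']:.2f} +/- {row['sem']:.3f} "
          f"(n={int(row['n'])})")
print(f"Welch t-test between genotypes: p = {delta['welch_p'].iloc[0]:.2e}")
print()
print("The mutant loses ~60% of this mRNA's TE under treatment while "
      "WT loses ~20% - the conditional-dependence signature, read out "
      "by an orthogonal, sequencing-free assay.")
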