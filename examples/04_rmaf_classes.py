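"""Classify somatic-mutation expression on the X chromosome via RMAF.

RMAF = mutant RNA reads / total RNA reads at the mutated site.  Mutations
with RMAF >= 0.75 are fully expressed, <= 0.25 silenced, and intermediate
values indicate bi-allelic expression (XCI escape).  Tumours with a large
Xi deletion cannot silence the mutant allele, so their expressed fraction
roughly doubles.
"""

from xaber import SimConfig, generate_cohort, rmaf

cohort = generate_cohort(SimConfig(n_samples=300, seed=4))
muts = rmaf.filter_silent(cohort.mutations)
muts = rmaf.annotate_mutations(muts, min_coverage=8)
x_muts = muts[muts["chromosome"] == "chrX"]

truth = cohort.truth.set_index("sample")["xi_group"]
table, chi2, p = rmaf.expression_class_table(x_muts, truth)
print("expression classes by Xi group:")
print(table)
frac = table["expressed"] / table.sum(axis=1)
print(f"\nexpressed fraction, Xi-deleted:   {frac['Xi-large-deletion']:.3f}")
print(f"expressed fraction, Xi-unaltered: {frac['Xi-unaltered']:.3f}")
print(f"ratio = {frac['Xi-large-deletion'] / frac['Xi-unaltered']:.2f}, "
      f"chi-square p = {p:.3g}")

tp53 = rmaf.sample_level_rmaf(muts, "TP53")
full_truth = cohort.truth.set_index("sample")
shared = tp53.index.intersection(full_truth.index)
cn_altered = (
    (full_truth.loc[shared, "xi_group"] == "Xi-large-deletion")
    | (full_truth.loc[shared, "xa_group"] == "Xa-large-amplification")
)
print(f"\nTP53 RMAF median, large CN aberration: "
      f"{tp53[shared][cn_altered].median():.2f}")
print(f"TP53 RMAF median, CN-quiet:            "
      f"{tp53[shared][~cn_altered].median():.2f}")
# TP53 RMAF near 1 signals loss of the wild-type allele (LOH); tumours
# carrying a large Xi deletion or Xa amplification are planted with TP53
# LOH, while CN-quiet TP53-mutants keep heterozygous (~0.5) expression.
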