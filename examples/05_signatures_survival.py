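"""Derive an Xi-deletion expression signature and test its prognostic value.

Differential expression (Xi-deleted vs fully unaltered tumours, subtype as
covariate, empirical-Bayes moderated t) selects downregulated X genes at
FDR <= 0.05; the signature is scored per sample (sig.score) and evaluated
with a median-split log-rank test and a Cox model over 20 years.
"""

from xaber import SimConfig, generate_cohort, pipeline

cohort = generate_cohort(SimConfig(n_samples=400, seed=5))
results = pipeline.run_pipeline(cohort)

for name, sig in results["signatures"].items():
    print(f"signature {name}: {len(sig['genes'])} genes "
          f"(direction {sig['provenance']['direction']})")

print()
for name, sv in results["survival"].items():
    if "cox" not in sv:
        continue
    cox = sv["cox"]["per_unit"]
    print(f"{name:18s} HR/unit {cox['hr']:6.2f} "
          f"[{cox['ci_low']:.2f}, {cox['ci_high']:.2f}]  "
          f"log-rank p = {sv['logrank_p']:.3g}")

ov = results.get("overlap_xi_deletion_high_methylation")
if ov:
    print(f"\nXi-deletion and high-methylation signatures share "
          f"{ov['n_shared']} genes "
          f"({ov['pct_of_xi_deletion']}% / {ov['pct_of_high_methylation']}%)")

oc = results.get("open_chromatin")
if oc and "welch_t" in oc:
    print(f"open-chromatin contrast: t = {oc['welch_t']:.2f}, p = {oc['p']:.3g} "
          f"({oc['n_inside']} genes inside vs {oc['n_outside']} outside peaks)")
# HR > 1 per unit score: tumours expressing the deletion signature more
# strongly (i.e. with lower expression of the signature genes) fare worse.
# The signature overlap mirrors the finding that Xi loss and promoter
# hypermethylation silence a shared set of X genes.
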