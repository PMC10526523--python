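# xaber — X-chromosome aberration analysis for breast cancer cohorts

In female somatic cells one X chromosome is transcriptionally silenced
(X-chromosome inactivation, XCI), largely maintained through promoter
methylation, with XIST as its master regulator and a minority of genes
escaping silencing.  Tumours can break this machinery in several ways:
by deleting most of the inactive X (Xi), by amplifying the active X (Xa),
or by shifting promoter methylation up or down.  `xaber` implements a
reusable pipeline that detects and quantifies these aberrations from
standard multi-omics inputs and evaluates their prognostic impact:

1. **XCI quantification** — array probes are assigned to gene promoters by
   TSS proximity (within 200 bp, falling back to 1500 bp), averaged to a
   gene x sample beta matrix, and summarised per sample as mean chrX
   promoter methylation.
2. **Copy-number cascade** — allele-specific copy-number segments are
   projected onto 1 Mb chrX bins; Ward clustering on a Gower (range-
   normalised Manhattan) dissimilarity splits samples into
   Xi-large-deletion vs Xi-unaltered (minor allele), then Xa-large-
   amplification vs Xa-unaltered (major allele, within Xi-unaltered), then
   high / low / unaltered methylation groups (within Xa-unaltered).
3. **RMAF expression classes** — the RNA-mutated allele frequency
   RMAF = alt / (alt + ref) of each X-linked somatic mutation is classed
   as `expressed` (RMAF ≥ 0.75), `non.expressed` (RMAF ≤ 0.25) or
   `escape` (in between), and contrasted across aberration groups.
4. **Signatures** — per-gene OLS of log2 expression on the group
   indicator with molecular-subtype covariates, empirical-Bayes variance
   moderation (posterior variance (d0·s0² + df·s²)/(d0 + df), moderated t
   on d0 + df degrees of freedom), BH FDR ≤ 0.05 with strict logFC sign;
   signatures are scored per sample as Σ wᵢx̃ᵢ / Σ|wᵢ| on expression
   robustly rescaled to [−1, 1].
5. **Survival** — median-split Kaplan–Meier curves with log-rank tests and
   Cox proportional-hazards models (Efron ties) over a 20-year horizon,
   plus the cohort cross-tab and rank-test statistics.

Because the cohorts this analysis targets are access-controlled, the
package ships a first-class synthetic-cohort generator
(`xaber.synthdata`) that emulates their statistical structure with known
per-sample ground truth, so the entire cascade is testable end to end.

## Worked example

```bash
python examples/03_copy_number_cascade.py
```

prints, for a 300-sample synthetic cohort:

```
tier sizes (nested):
  all                  300
  xi_unaltered         201
  xa_unaltered         117
  with_methylation     117
  selected_unaltered   86
ARI vs planted truth, Xi           tier: 1.000
ARI vs planted truth, Xa           tier: 1.000
ARI vs planted truth, methylation  tier: 1.000
```

Of 300 tumours, 99 carry a large Xi deletion; of the 201 remaining, 84
carry a large Xa amplification; the methylation tier subdivides the quiet
117, leaving 86 tumours unaltered at every tier (the contrast group for
the signatures).  An adjusted Rand index of 1.0 against the planted truth
means each clustering tier recovered its groups exactly.  The other
examples cover simulation (`01`), methylation quantification (`02`), RMAF
classes (`04` — Xi-deleted tumours show ~2x the fraction of fully
expressed X mutations, and TP53 loss of heterozygosity tracks large CN
aberrations), and signatures + survival (`05`).

The same pipeline is available from the shell:

```bash
xaber simulate --seed 1 --outdir cohort/
xaber run --seed 1 --cohort-dir cohort/ --outdir results/
xaber report --results-dir results/
```

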