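"""Promoter methylation: probe-to-gene aggregation and XCI quantification.

Array probes are assigned to a gene promoter by proximity to the
transcription start site: probes within 200 bp of the TSS if any exist,
otherwise probes within 1500 bp, otherwise the gene gets no methylation
value.  Gene-level beta is the mean of assigned probes' beta-values;
missing betas are propagated, never imputed.  Per-sample X-inactivation
level is summarised as the unweighted mean promoter beta over chrX genes,
and samples are clustered into high / low / unaltered methylation groups
with the same Gower + Ward machinery used for copy number.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import xcna

METH_HIGH = "high"
METH_LOW = "low"
METH_UNALTERED = "unaltered"


def assign_probes_to_genes(
    probes: pd.DataFrame,
    gene_models: pd.DataFrame,
    near_bp: int = 200,
    far_bp: int = 1500,
) -> dict[str, list[str]]:
    """Map each gene to its promoter probes by TSS proximity.

    A gene receives its probes within ``near_bp`` of the TSS; if there are
    none, its probes within ``far_bp``; otherwise it is absent from the
    mapping.  Distance is strand-agnostic |probe position - TSS|.  A probe
    may serve several genes whose windows contain it.

    ``probes`` needs columns (probe, chromosome, position); ``gene_models``
    needs (gene, chromosome, tss).
    """
    mapping: dict[str, list[str]] = {}
    by_chrom = {c: g for c, g in probes.groupby("chromosome")}
    for row in gene_models.itertuples(index=False):
        chrom_probes = by_chrom.get(row.chromosome)
        if chrom_probes is None:
            continue
        dist = (chrom_probes["position"] - row.tss).abs()
        near = chrom_probes.loc[dist <= near_bp, "probe"]
        if len(near):
            mapping[row.gene] = list(near)
            continue
        far = chrom_probes.loc[dist <= far_bp, "probe"]
        if len(far):
            mapping[row.gene] = list(far)
    return mapping


def gene_promoter_beta(
    beta: pd.DataFrame, mapping: dict[str, list[str]]
) -> pd.DataFrame:
    """Aggregate a probe-by-sample beta matrix to gene level.

    Each entry is the mean over the gene's assigned probes, ignoring
    missing betas; it is missing when every assigned probe is missing for
    that sample.
    """
    rows = {}
    for gene, probe_ids in mapping.items():
        absent = [p for p in probe_ids if p not in beta.index]
        if absent:
            raise KeyError(
                f"probes {absent} assigned to gene {gene!r} are absent from the beta matrix"
            )
        rows[gene] = beta.loc[probe_ids].mean(axis=0, skipna=True)
    out = pd.DataFrame(rows).T
    out.index.name = "gene"
    if out.empty:
        out = pd.DataFrame(columns=beta.columns)
        out.index.name = "gene"
    return out


def mean_x_promoter_methylation(
    gene_beta: pd.DataFrame, gene_models: pd.DataFrame, x_chrom: str = "chrX"
) -> pd.Series:
    """Per-sample mean promoter beta over chrX genes (XCI level proxy)."""
    x_genes = gene_models.loc[gene_models["chromosome"] == x_chrom, "gene"]
    present = [g for g in x_genes if g in gene_beta.index]
    if not present:
        raise ValueError("no chrX genes present in the gene-level beta matrix")
    out = gene_beta.loc[present].mean(axis=0, skipna=True)
    out.name = "mean_x_beta"
    return out


def cluster_methylation_groups(gene_beta_x: pd.DataFrame, k: int = 3) -> pd.Series:
    """Cluster samples into high / low / unaltered X-methylation groups.

    Ward clustering on the Gower dissimilarity of samples (columns of the
    gene-by-sample beta matrix), cut at ``k``; clusters are named by the
    rank of their centroid mean beta — highest centroid is ``high``, lowest
    is ``low``, everything between is ``unaltered``.  With ``k=1`` every
    sample is ``unaltered``.
    """
    samples = gene_beta_x.columns
    n = len(samples)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if k == 1 or n == 1:
        return pd.Series(METH_UNALTERED, index=samples, name="methylation_group")
    X = gene_beta_x.to_numpy(float).T  # samples as rows
    try:
        D = xcna.gower_dissimilarity(X)
    except ValueError:
        warnings.warn(
            "all samples have identical methylation; single unaltered group"
        )
        return pd.Series(METH_UNALTERED, index=samples, name="methylation_group")
    labels = xcna.ward_cluster(D, k)
    centroids = {
        c: float(np.nanmean(X[labels == c])) for c in np.unique(labels)
    }
    ranked = sorted(centroids, key=centroids.get)
    names = {c: METH_UNALTERED for c in ranked}
    names[ranked[-1]] = METH_HIGH
    names[ranked[0]] = METH_LOW
    out = pd.Series([names[c] for c in labels], index=samples, name="methylation_group")
    return out
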