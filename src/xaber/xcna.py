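"""Allele-specific copy-number binning and the Xi/Xa clustering cascade.

Tumours are classified from allele-specific copy-number segments projected
onto fixed chrX bins.  The inactive X (Xi) is proxied by the minor allele —
a large Xi deletion shows as minor copy number 0 over most of the
chromosome — and the active X (Xa) by the major allele, with amplification
showing as major copy number 2-3.  Samples are clustered with Ward linkage
on a Gower (range-normalised Manhattan) dissimilarity, mirroring the
daisy + hclust idiom, and the cascade nests three tiers: Xi grouping on all
samples, Xa grouping within Xi-unaltered samples, and promoter-methylation
grouping within Xa-unaltered samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

XI_DELETION = "Xi-large-deletion"
XI_UNALTERED = "Xi-unaltered"
XA_AMPLIFICATION = "Xa-large-amplification"
XA_UNALTERED = "Xa-unaltered"
NOT_APPLICABLE = "not-applicable"

SEGMENT_COLUMNS = ["sample", "chromosome", "start", "end", "major_cn", "minor_cn"]


def make_bins(n_bins: int, bin_size_bp: int) -> pd.DataFrame:
    """Tile a chromosome with ``n_bins`` equal bins (1-based inclusive)."""
    if n_bins < 1 or bin_size_bp < 1:
        raise ValueError("n_bins and bin_size_bp must be positive")
    starts = np.arange(n_bins, dtype=np.int64) * bin_size_bp + 1
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "start": starts, "end": starts + bin_size_bp - 1}
    )


@dataclass
class BinnedCN:
    """Sample-by-bin copy-number matrix with a mask of imputed bins.

    ``values`` holds per-bin length-weighted mean copy number; bins with no
    segment coverage are filled with the sample's modal copy number and
    flagged True in ``uncovered``.
    """

    values: pd.DataFrame
    uncovered: pd.DataFrame


def bin_segments(
    segments: pd.DataFrame, bins: pd.DataFrame, allele: str
) -> BinnedCN:
    """Project segments onto bins as length-weighted mean copy number.

    Parameters
    ----------
    segments
        Long table with columns ``sample, chromosome, start, end,
        major_cn, minor_cn`` (1-based inclusive coordinates).
    bins
        Non-overlapping tiling from :func:`make_bins`.
    allele
        ``"minor"`` or ``"major"`` — which allele's copy number to project.
    """
    if allele not in ("minor", "major"):
        raise ValueError(f"allele must be 'minor' or 'major', got {allele!r}")
    cn_col = f"{allele}_cn"
    missing = [c for c in SEGMENT_COLUMNS if c not in segments.columns]
    if missing:
        raise ValueError(f"segments table lacks columns: {missing}")

    bin_starts = bins["start"].to_numpy(np.int64)
    bin_ends = bins["end"].to_numpy(np.int64)
    n_bins = len(bins)
    samples = list(pd.unique(segments["sample"]))

    values = np.zeros((len(samples), n_bins))
    uncovered = np.zeros((len(samples), n_bins), dtype=bool)

    for i, sample in enumerate(samples):
        sub = segments[segments["sample"] == sample].sort_values("start")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        cns = sub[cn_col].to_numpy(float)
        if np.any(starts[1:] <= ends[:-1]):
            bad = np.nonzero(starts[1:] <= ends[:-1])[0]
            offenders = sub.iloc[np.unique(np.r_[bad, bad + 1])]
            raise ValueError(
                f"overlapping segments for sample {sample!r}:\n{offenders}"
            )
        num = np.zeros(n_bins)
        den = np.zeros(n_bins)
        for s, e, cn in zip(starts, ends, cns):
            overlap = np.minimum(bin_ends, e) - np.maximum(bin_starts, s) + 1
            overlap = np.clip(overlap, 0, None).astype(float)
            num += overlap * cn
            den += overlap
        covered = den > 0
        values[i, covered] = num[covered] / den[covered]
        if not covered.all():
            if not covered.any():
                raise ValueError(f"sample {sample!r} has no chrX coverage")
            # modal CN over covered genome, length-weighted; ties -> smaller
            lengths = (ends - starts + 1).astype(float)
            order = np.argsort(cns, kind="stable")
            uniq, inv = np.unique(cns[order], return_inverse=True)
            mass = np.bincount(inv, weights=lengths[order])
            modal = uniq[np.argmax(mass)]
            values[i, ~covered] = modal
            uncovered[i, ~covered] = True

    idx = pd.Index(samples, name="sample")
    return BinnedCN(
        values=pd.DataFrame(values, index=idx, columns=bins["bin"]),
        uncovered=pd.DataFrame(uncovered, index=idx, columns=bins["bin"]),
    )


def gower_dissimilarity(matrix) -> np.ndarray:
    """Gower dissimilarity for numeric data (samples are rows).

    d(i, j) = mean over usable columns of |x_i - x_j| / range(column).
    Columns with zero range are skipped; entries missing in either row are
    skipped pairwise.  Raises if every column has zero range.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rng_ = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
    usable = np.nan_to_num(rng_) > 0
    if not usable.any():
        raise ValueError("all columns have zero range; Gower undefined")
    Xs = X[:, usable] / rng_[usable]
    n = Xs.shape[0]
    if not np.isnan(Xs).any():
        diff = np.abs(Xs[:, None, :] - Xs[None, :, :])
        return diff.mean(axis=2)
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for k in range(Xs.shape[1]):
        col = Xs[:, k]
        ok = ~np.isnan(col)
        pair_ok = np.outer(ok, ok)
        d = np.abs(np.subtract.outer(np.nan_to_num(col), np.nan_to_num(col)))
        num += np.where(pair_ok, d, 0.0)
        cnt += pair_ok
    if (cnt == 0).any():
        raise ValueError("some sample pairs share no observed columns")
    D = num / cnt
    np.fill_diagonal(D, 0.0)
    return D


def ward_cluster(dissimilarity: np.ndarray, k: int) -> np.ndarray:
    """Cut a Ward tree built on a precomputed dissimilarity at k clusters.

    Returns integer labels in 0..k-1 (arbitrary but deterministic order).
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return np.zeros(n, dtype=int)
    if k == n:
        return np.arange(n)
    Z = linkage(squareform(D, checks=False), method="ward")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def _label_two_clusters(
    matrix: np.ndarray,
    labels: np.ndarray,
    altered_name: str,
    unaltered_name: str,
    stat_fn,
) -> pd.Series:
    """Name the cluster with the larger aberration statistic as altered.

    Tie on the statistic -> the larger cluster is called unaltered
    (conservative); a further tie falls to the cluster of the first sample.
    """
    per_sample = stat_fn(matrix)
    stats, sizes = {}, {}
    for c in np.unique(labels):
        stats[c] = float(per_sample[labels == c].mean())
        sizes[c] = int((labels == c).sum())
    ordered = sorted(
        stats, key=lambda c: (stats[c], -sizes[c], c != labels[0]), reverse=True
    )
    altered = ordered[0]
    if len(ordered) > 1 and np.isclose(stats[ordered[0]], stats[ordered[1]]):
        # statistic tie: larger cluster is unaltered
        altered = min(stats, key=lambda c: (sizes[c], c == labels[0]))
    return pd.Series(
        np.where(labels == altered, altered_name, unaltered_name)
    )


def assign_xi_groups(minor_matrix: pd.DataFrame, k: int = 2) -> pd.Series:
    """Cluster samples on the minor-allele bin matrix into Xi groups.

    The cluster with the larger mean fraction of bins below copy number 0.5
    is labelled Xi-large-deletion.  If all samples are identical the split
    degenerates and every sample is Xi-unaltered (with a warning).
    """
    if len(minor_matrix) < 2:
        raise ValueError("need at least 2 samples for Xi grouping")
    X = minor_matrix.to_numpy(float)
    try:
        D = gower_dissimilarity(X)
    except ValueError:
        warnings.warn("all samples identical; emitting a single Xi-unaltered group")
        return pd.Series(XI_UNALTERED, index=minor_matrix.index, name="xi_group")
    labels = ward_cluster(D, k)
    out = _label_two_clusters(
        X, labels, XI_DELETION, XI_UNALTERED, lambda m: (m < 0.5).mean(axis=1)
    )
    out.index = minor_matrix.index
    out.name = "xi_group"
    return out


def assign_xa_groups(major_matrix: pd.DataFrame, k: int = 2) -> pd.Series:
    """Cluster Xi-unaltered samples on the major allele into Xa groups.

    The cluster with the larger mean fraction of bins above copy number 1.5
    is labelled Xa-large-amplification.
    """
    if len(major_matrix) == 0:
        return pd.Series(dtype=object, name="xa_group")
    if len(major_matrix) < 2:
        raise ValueError("need at least 2 samples for Xa grouping")
    X = major_matrix.to_numpy(float)
    try:
        D = gower_dissimilarity(X)
    except ValueError:
        warnings.warn("all samples identical; emitting a single Xa-unaltered group")
        return pd.Series(XA_UNALTERED, index=major_matrix.index, name="xa_group")
    labels = ward_cluster(D, k)
    out = _label_two_clusters(
        X, labels, XA_AMPLIFICATION, XA_UNALTERED, lambda m: (m > 1.5).mean(axis=1)
    )
    out.index = major_matrix.index
    out.name = "xa_group"
    return out


@dataclass
class CascadeResult:
    """Per-sample assignments from the three-tier cascade plus tier sizes."""

    assignments: pd.DataFrame
    tier_sizes: dict = field(default_factory=dict)


def run_cascade(
    segments: pd.DataFrame,
    bins: pd.DataFrame,
    gene_beta_x: pd.DataFrame | None = None,
    k_cn: int = 2,
    k_meth: int = 3,
) -> CascadeResult:
    """Three-tier grouping: Xi deletion, then Xa amplification, then
    X-promoter-methylation group, each tier nested in the previous tier's
    unaltered samples.

    ``gene_beta_x`` is a gene-by-sample promoter beta matrix restricted to
    chrX genes; samples absent from it get methylation_group
    ``not-applicable``.  ``selected_unaltered`` marks samples unaltered at
    all three tiers (the contrast group for the expression signatures).
    """
    from . import methylation  # local import: two-way module relationship

    minor = bin_segments(segments, bins, "minor")
    major = bin_segments(segments, bins, "major")
    samples = minor.values.index
    if len(samples) == 0:
        raise ValueError("no samples in segments table")

    xi = assign_xi_groups(minor.values, k=k_cn)
    xa = pd.Series(NOT_APPLICABLE, index=samples, name="xa_group")
    xi_un = xi.index[xi == XI_UNALTERED]
    if len(xi_un) >= 2:
        xa.loc[xi_un] = assign_xa_groups(major.values.loc[xi_un], k=k_cn)
    elif len(xi_un) == 1:
        xa.loc[xi_un] = XA_UNALTERED

    meth = pd.Series(NOT_APPLICABLE, index=samples, name="methylation_group")
    xa_un = xa.index[xa == XA_UNALTERED]
    if gene_beta_x is not None and len(xa_un) > 0:
        with_meth = [s for s in xa_un if s in gene_beta_x.columns]
        if len(with_meth) >= k_meth:
            meth.loc[with_meth] = methylation.cluster_methylation_groups(
                gene_beta_x[with_meth], k=k_meth
            )
        elif with_meth:
            meth.loc[with_meth] = "unaltered"

    selected = (xi == XI_UNALTERED) & (xa == XA_UNALTERED) & (meth == "unaltered")
    assignments = pd.DataFrame(
        {
            "xi_group": xi,
            "xa_group": xa,
            "methylation_group": meth,
            "selected_unaltered": selected,
        }
    )
    assignments.index.name = "sample"
    tier_sizes = {
        "all": int(len(samples)),
        "xi_unaltered": int((xi == XI_UNALTERED).sum()),
        "xa_unaltered": int((xa == XA_UNALTERED).sum()),
        "with_methylation": int((meth != NOT_APPLICABLE).sum()),
        "selected_unaltered": int(selected.sum()),
    }
    return CascadeResult(assignments=assignments, tier_sizes=tier_sizes)
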