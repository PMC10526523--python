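"""Covariate-adjusted differential expression and prognostic signatures.

Per-gene ordinary least squares of log2 expression on a group indicator
plus molecular-subtype dummies, followed by empirical-Bayes variance
moderation: gene-wise residual variances s_g^2 are shrunk towards a
scaled-inverse-chi-square prior (d0, s0^2) fitted by method of moments on
log variances, and the moderated t uses the posterior variance

    s~_g^2 = (d0 * s0^2 + df * s_g^2) / (d0 + df)

on d0 + df degrees of freedom.  Signatures are the genes passing an FDR
threshold with a strict log-fold-change sign, weighted +/-1, and scored
per sample by a weighted mean of robustly rescaled expression
(the sig.score construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


def _build_design(group_indicator: pd.Series, covariates: pd.Series | None):
    """Intercept + group + treatment-coded subtype dummies (modal level as
    reference).  Returns (matrix, column names)."""
    cols = [np.ones(len(group_indicator)), group_indicator.to_numpy(float)]
    names = ["intercept", "group"]
    if covariates is not None:
        cov = covariates.loc[group_indicator.index]
        ref = cov.value_counts().idxmax()
        for level in sorted(set(cov) - {ref}):
            cols.append((cov == level).to_numpy(float))
            names.append(f"subtype[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via QR diagonal
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")
    return X, names


def fit_gene_models(
    expression: pd.DataFrame,
    group_indicator: pd.Series,
    covariates: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene OLS of expression on [intercept, group, subtype dummies].

    ``expression`` is genes x samples (log2 scale); ``group_indicator`` is
    0/1 per sample.  Returns a per-gene frame with the group coefficient as
    ``logFC``, its standard error, residual variance ``sigma2`` and
    residual ``df``.
    """
    samples = group_indicator.index
    for g in (0, 1):
        if (group_indicator == g).sum() < 2:
            raise ValueError(f"need at least 2 samples with group indicator {g}")
    Y = expression[samples].to_numpy(float).T  # samples x genes
    X, _ = _build_design(group_indicator, covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError("more design columns than samples")
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ X.T @ Y  # p x genes
    resid = Y - X @ coef
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    c_group = XtX_inv[1, 1]
    se = np.sqrt(c_group * sigma2)
    return pd.DataFrame(
        {
            "logFC": coef[1],
            "se": se,
            "sigma2": sigma2,
            "df": df,
            "unscaled_se2": c_group,
        },
        index=pd.Index(expression.index, name="gene"),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the monotone map)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


@dataclass
class ModerationResult:
    prior_df: float  # d0; inf when the variances are under-dispersed
    prior_var: float  # s0^2
    posterior_var: np.ndarray


def moderate_variances(residual_variances, df) -> ModerationResult:
    """Fit a scaled-inverse-chi-square prior to gene variances and shrink.

    Method of moments on log variances: with z_g = log s_g^2,
    E[z] = log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2); d0 solves the variance
    identity via the trigamma inverse.  When the empirical variance of z is
    no larger than trigamma(df/2) the prior is degenerate (d0 = inf) and
    every posterior variance equals s0^2.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to fit the variance prior")
    if np.any(s2 <= 0):
        raise ValueError("residual variances must be positive")
    df = float(df)
    z = np.log(s2)
    if np.ptp(z) == 0.0:
        # degenerate input: no spread at all, so no sampling noise to
        # correct for — pool exactly to the common value
        return ModerationResult(
            prior_df=np.inf, prior_var=float(s2[0]),
            posterior_var=np.full_like(s2, s2[0]),
        )
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
        post = np.full_like(s2, s02)
    return ModerationResult(prior_df=d0, prior_var=s02, posterior_var=post)


def moderated_t_table(
    fits: pd.DataFrame, moderation: ModerationResult | None = None
) -> pd.DataFrame:
    """Moderated t statistics, p-values and BH-adjusted FDR for a fit table.

    With ``moderation=None`` the prior is fitted here.  ``prior_df = 0``
    (or an infinite-variance fit) reduces exactly to the ordinary t test.
    """
    if moderation is None:
        moderation = moderate_variances(fits["sigma2"].to_numpy(), fits["df"].iloc[0])
    d0 = moderation.prior_df
    df = fits["df"].to_numpy(float)
    post = moderation.posterior_var
    se_mod = np.sqrt(fits["unscaled_se2"].to_numpy() * post)
    t = fits["logFC"].to_numpy() / se_mod
    df_total = df + (0.0 if not np.isfinite(d0) else d0)
    if np.isfinite(d0):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    out = fits.copy()
    out["t_mod"] = t
    out["p"] = p
    out["fdr"] = bh_fdr(p)
    out["prior_df"] = d0
    out["prior_var"] = moderation.prior_var
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_analysis(
    expression: pd.DataFrame,
    group_indicator: pd.Series,
    covariates: pd.Series | None = None,
) -> pd.DataFrame:
    """Fit, moderate and test in one call (the standard DE entry point)."""
    fits = fit_gene_models(expression, group_indicator, covariates)
    return moderated_t_table(fits)


@dataclass
class Signature:
    """A directed gene list with +/-1 weights and its provenance."""

    name: str
    genes: list  # list of (gene, weight)
    provenance: dict = field(default_factory=dict)

    @property
    def gene_names(self) -> list:
        return [g for g, _ in self.genes]


def select_signature(
    de_results: pd.DataFrame,
    direction: str,
    fdr_max: float = 0.05,
    name: str = "signature",
) -> Signature:
    """Genes at FDR <= fdr_max with a strictly signed logFC; weight = sign.

    ``direction='down'`` keeps logFC < 0, ``'up'`` keeps logFC > 0
    (logFC exactly 0 is excluded either way).
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    keep = de_results["fdr"] <= fdr_max
    keep &= de_results["logFC"] < 0 if direction == "down" else de_results["logFC"] > 0
    genes = [
        (g, int(np.sign(lfc)))
        for g, lfc in de_results.loc[keep, "logFC"].items()
    ]
    if not genes:
        warnings.warn(f"empty signature {name!r} (no gene passed the filters)")
    return Signature(
        name=name,
        genes=genes,
        provenance={"direction": direction, "fdr_max": fdr_max, "n_genes": len(genes)},
    )


def sig_score(
    expression: pd.DataFrame,
    signature: Signature,
    quantiles: tuple = (0.025, 0.975),
) -> pd.Series:
    """Per-sample signature score: weighted mean of rescaled expression.

    Each signature gene is rescaled to [-1, 1] by mapping its ``quantiles``
    (default 2.5% / 97.5%) to the interval ends, clipping beyond; the score
    is sum(w_i * x~_i) / sum(|w_i|).  Genes absent from the matrix are
    dropped with a warning; a signature with no usable gene raises.
    """
    usable = [(g, w) for g, w in signature.genes if g in expression.index]
    dropped = len(signature.genes) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} signature gene(s) absent from the expression matrix")
    if not usable:
        raise ValueError(f"no usable genes for signature {signature.name!r}")
    genes = [g for g, _ in usable]
    w = np.array([wt for _, wt in usable], dtype=float)
    X = expression.loc[genes].to_numpy(float)
    lo = np.quantile(X, quantiles[0], axis=1, keepdims=True)
    hi = np.quantile(X, quantiles[1], axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    span[flat.reshape(-1, 1)] = 1.0
    Xs = np.clip((X - lo) / span, 0.0, 1.0) * 2.0 - 1.0
    Xs[flat] = 0.0
    scores = (w[:, None] * Xs).sum(axis=0) / np.abs(w).sum()
    return pd.Series(scores, index=expression.columns, name=f"{signature.name}_score")


def hypergeometric_enrichment(
    signature_genes, region_genes, universe
) -> float:
    """Upper-tail hypergeometric probability of >= the observed overlap.

    ``P(K >= k)`` drawing |signature| genes from a universe containing the
    region set; used e.g. for pseudoautosomal-region enrichment.
    """
    universe = set(universe)
    sig = set(signature_genes)
    region = set(region_genes)
    if not sig <= universe:
        raise ValueError("signature genes must be a subset of the universe")
    if not region <= universe:
        raise ValueError("region genes must be a subset of the universe")
    k = len(sig & region)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(region), len(sig)))


def signature_overlap(genes_a, genes_b):
    """Shared genes and the integer percentage of each signature they form."""
    a, b = set(genes_a), set(genes_b)
    shared = sorted(a & b)

    def pct(num, den):
        return int(np.floor(100.0 * num / den + 0.5)) if den else 0

    return shared, pct(len(shared), len(a)), pct(len(shared), len(b))


def open_chromatin_contrast(
    gene_beta: pd.DataFrame,
    signature_genes,
    gene_models: pd.DataFrame,
    peaks: pd.DataFrame,
    window_bp: int = 1000,
):
    """Promoter methylation of signature genes inside vs outside open chromatin.

    A gene is "inside" iff its TSS +/- ``window_bp`` intersects any ATAC
    peak (peaks are BED-style 0-based half-open; converted here).  Welch's
    two-sample t-test compares the per-gene mean promoter beta between the
    inside and outside sets.  Returns (inside_flags, t, p).
    """
    models = gene_models.set_index("gene")
    present = [g for g in signature_genes if g in models.index and g in gene_beta.index]
    if not present:
        raise ValueError("no signature gene with both coordinates and methylation")
    peak_start = peaks["start"].to_numpy(np.int64) + 1  # to 1-based inclusive
    peak_end = peaks["end"].to_numpy(np.int64)
    peak_chrom = peaks["chromosome"].to_numpy()
    inside = {}
    for g in present:
        tss = int(models.at[g, "tss"])
        chrom = models.at[g, "chromosome"]
        lo, hi = tss - window_bp, tss + window_bp
        hit = (peak_chrom == chrom) & (peak_start <= hi) & (peak_end >= lo)
        inside[g] = bool(hit.any())
    flags = pd.Series(inside, name="inside_open_chromatin")
    mean_beta = gene_beta.loc[present].mean(axis=1, skipna=True)
    grp_in = mean_beta[flags]
    grp_out = mean_beta[~flags]
    if grp_in.empty or grp_out.empty:
        raise ValueError("one of the inside/outside gene sets is empty")
    t, p = stats.ttest_ind(grp_in, grp_out, equal_var=False)
    return flags, float(t), float(p)
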