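"""RNA-mutated allele frequency (RMAF) and somatic-mutation expression classes.

For a somatic mutation with RNA-seq read counts (alt, ref) at the mutated
site, RMAF = alt / (alt + ref).  On the X chromosome the RMAF of a
heterozygous mutation reads out X-inactivation: a mutation on the active X
with a silenced wild-type allele (or a hemizygous mutation after Xi loss)
approaches RMAF 1, a silenced mutant allele approaches 0, and bi-allelic
expression (XCI escape) sits near 0.5.  Mutations are classified as
``expressed`` (RMAF >= 0.75), ``non.expressed`` (RMAF <= 0.25) or
``escape`` (strictly between); both boundary values fall to the outer
classes.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSED = "expressed"
NON_EXPRESSED = "non.expressed"
ESCAPE = "escape"

RMAF_UPPER = 0.75
RMAF_LOWER = 0.25

DEFAULT_MIN_COVERAGE = 8


def filter_silent(mutations: pd.DataFrame, class_col: str = "classification") -> pd.DataFrame:
    """Drop mutations annotated exactly 'Silent'; order otherwise preserved."""
    if class_col not in mutations.columns:
        raise KeyError(f"mutation table lacks column {class_col!r}")
    return mutations[mutations[class_col] != "Silent"].copy()


def compute_rmaf(
    alt_count, ref_count, min_coverage: int = DEFAULT_MIN_COVERAGE
):
    """RMAF = alt / (alt + ref), or NaN below the coverage floor.

    Accepts scalars or aligned arrays; negative counts raise.
    """
    alt = np.asarray(alt_count, dtype=float)
    ref = np.asarray(ref_count, dtype=float)
    if np.any(alt < 0) or np.any(ref < 0):
        raise ValueError("read counts must be non-negative")
    total = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total >= min_coverage, alt / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(alt_count) and np.isscalar(ref_count):
        return float(out) if not np.isnan(out) else float("nan")
    return out


def classify_expression(rmaf):
    """Map an RMAF to its expression class (boundaries to the outer classes)."""
    if np.isscalar(rmaf):
        if rmaf is None or (isinstance(rmaf, float) and math.isnan(rmaf)):
            raise ValueError("RMAF is undefined; filter low-coverage mutations first")
        if rmaf >= RMAF_UPPER:
            return EXPRESSED
        if rmaf <= RMAF_LOWER:
            return NON_EXPRESSED
        return ESCAPE
    arr = np.asarray(rmaf, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("RMAF is undefined; filter low-coverage mutations first")
    out = np.full(arr.shape, ESCAPE, dtype=object)
    out[arr >= RMAF_UPPER] = EXPRESSED
    out[arr <= RMAF_LOWER] = NON_EXPRESSED
    return out


def annotate_mutations(
    mutations: pd.DataFrame, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.DataFrame:
    """Add ``rmaf`` and ``expression_class`` columns to a mutation table.

    Mutations below the coverage floor keep NaN RMAF and no class.
    """
    out = mutations.copy()
    out["rmaf"] = compute_rmaf(
        out["alt_count"].to_numpy(), out["ref_count"].to_numpy(), min_coverage
    )
    covered = out["rmaf"].notna()
    out["expression_class"] = pd.NA
    if covered.any():
        out.loc[covered, "expression_class"] = classify_expression(
            out.loc[covered, "rmaf"].to_numpy()
        )
    return out


def expression_class_table(
    mutations: pd.DataFrame, group_labels: pd.Series
):
    """Cross-tabulate expression classes against sample groups.

    Returns ``(table, chi2, p)`` where ``table`` is groups x classes and
    the test is Pearson's chi-square without continuity correction.  Every
    mutation's sample must carry a group label; a single group or an
    all-zero margin raises.
    """
    classified = mutations[mutations["expression_class"].notna()]
    unlabelled = set(classified["sample"]) - set(group_labels.index)
    if unlabelled:
        raise KeyError(f"samples without a group label: {sorted(unlabelled)[:5]}")
    groups = classified["sample"].map(group_labels)
    table = pd.crosstab(groups, classified["expression_class"])
    table = table.reindex(columns=[EXPRESSED, NON_EXPRESSED, ESCAPE]).dropna(axis=1, how="all")
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least two groups and two classes")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return table, float(chi2), float(p)


def sample_level_rmaf(
    mutations: pd.DataFrame, gene: str, min_coverage: int = DEFAULT_MIN_COVERAGE
) -> pd.Series:
    """Per-sample mean RMAF over one gene's qualifying mutations.

    Used e.g. for TP53, where RMAF near 1 signals loss of heterozygosity.
    Samples without a covered mutation in the gene are absent.
    """
    sub = mutations[mutations["gene"] == gene]
    if sub.empty:
        raise KeyError(f"gene {gene!r} absent from the mutation table")
    rmafs = compute_rmaf(
        sub["alt_count"].to_numpy(), sub["ref_count"].to_numpy(), min_coverage
    )
    sub = sub.assign(rmaf=rmafs).dropna(subset=["rmaf"])
    if sub.empty:
        warnings.warn(f"no mutation in {gene!r} passes the coverage floor")
    out = sub.groupby("sample")["rmaf"].mean()
    out.name = f"{gene}_rmaf"
    return out
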