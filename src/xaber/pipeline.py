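"""End-to-end orchestration of the X-aberration analysis.

``run_pipeline`` executes the full cascade on a cohort (synthetic or read
from disk): promoter-methylation aggregation, the three-tier Xi / Xa /
methylation grouping, subtype and TP53 cross-tabs, RMAF expression-class
analysis, the four differential-expression signatures (Xi-deletion down,
Xa-amplification up, high-methylation down, low-methylation up), PAR
enrichment, signature overlap, the open-chromatin methylation contrast,
and survival evaluation of every signature score.  Results are returned as
a plain dict and optionally written as a results tree with a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import de_signatures as de
from . import methylation, rmaf, survival_stats, synthdata, xcna


DEFAULT_PARAMS = {
    "near_bp": 200,
    "far_bp": 1500,
    "min_coverage": 8,
    "fdr_max": 0.05,
    "k_cn": 2,
    "k_meth": 3,
    "signature_horizon_years": 20.0,
    "subtype_horizon_years": 5.0,
    "open_chromatin_window_bp": 1000,
}


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(
    cohort: synthdata.SyntheticCohort,
    params: dict | None = None,
    outdir=None,
) -> dict:
    """Run the whole analysis on one cohort; optionally write results.

    Returns a nested dict with assignments, tier sizes, cross-tabs, the
    RMAF contingency analysis, the four signatures with per-sample scores
    and survival results, enrichment / overlap / open-chromatin statistics
    and (when ground truth is present) per-tier adjusted Rand indices.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    cfg = cohort.config
    results: dict = {"params": p}

    # ---- stage 1: promoter methylation ----------------------------------
    mapping = methylation.assign_probes_to_genes(
        cohort.probes, cohort.gene_models, near_bp=p["near_bp"], far_bp=p["far_bp"]
    )
    gene_beta = methylation.gene_promoter_beta(cohort.beta, mapping)
    gene_beta = gene_beta.dropna(axis=1, how="all")
    x_genes = cohort.gene_models.loc[
        cohort.gene_models["chromosome"] == synthdata.CHRX, "gene"
    ]
    gene_beta_x = gene_beta.loc[[g for g in x_genes if g in gene_beta.index]]
    mean_x_beta = methylation.mean_x_promoter_methylation(
        gene_beta, cohort.gene_models
    )

    # ---- stage 2: the clustering cascade --------------------------------
    bins = xcna.make_bins(cfg.n_bins, cfg.bin_size_bp)
    cascade = xcna.run_cascade(
        cohort.segments, bins, gene_beta_x=gene_beta_x,
        k_cn=p["k_cn"], k_meth=p["k_meth"],
    )
    assignments = cascade.assignments
    clinical = cohort.clinical.set_index("sample").loc[assignments.index]
    results["tier_sizes"] = cascade.tier_sizes

    # ---- stage 3: cross-tabs against subtype and TP53 -------------------
    xi_del = assignments["xi_group"] == xcna.XI_DELETION
    crosstabs = {}
    sub_levels = list(pd.unique(clinical["subtype"]))
    nums = [int((xi_del & (clinical["subtype"] == s)).sum()) for s in sub_levels]
    dens = [int((clinical["subtype"] == s).sum()) for s in sub_levels]
    if all(d > 0 for d in dens) and len(dens) >= 2:
        pct, chi2, pv = survival_stats.crosstab_percent(nums, dens)
        crosstabs["xi_deletion_by_subtype"] = {
            "categories": sub_levels, "numerators": nums, "denominators": dens,
            "percent": pct.tolist(), "chi2": chi2, "p": pv,
        }
    for label, mask in (
        ("xi_deletion_by_tp53", xi_del),
        (
            "xa_amplification_by_tp53",
            assignments["xa_group"] == xcna.XA_AMPLIFICATION,
        ),
    ):
        eligible = (
            assignments["xa_group"] != xcna.NOT_APPLICABLE
            if label.startswith("xa")
            else pd.Series(True, index=assignments.index)
        )
        nums, dens = [], []
        for status in ("mut", "wt"):
            in_status = (clinical["tp53_status"] == status) & eligible
            nums.append(int((mask & in_status).sum()))
            dens.append(int(in_status.sum()))
        if all(d > 0 for d in dens):
            pct, chi2, pv = survival_stats.crosstab_percent(nums, dens)
            crosstabs[label] = {
                "categories": ["mut", "wt"], "numerators": nums,
                "denominators": dens, "percent": pct.tolist(),
                "chi2": chi2, "p": pv,
            }
    results["crosstabs"] = crosstabs

    # ---- stage 4: RMAF and expression classes ---------------------------
    muts = rmaf.filter_silent(cohort.mutations)
    muts = rmaf.annotate_mutations(muts, min_coverage=p["min_coverage"])
    x_muts = muts[muts["chromosome"] == synthdata.CHRX]
    rmaf_results: dict = {"n_mutations_x": int(len(x_muts))}
    try:
        table, chi2, pv = rmaf.expression_class_table(
            x_muts, assignments["xi_group"]
        )
        frac = (
            table[rmaf.EXPRESSED] / table.sum(axis=1)
            if rmaf.EXPRESSED in table
            else None
        )
        rmaf_results["class_table"] = table.to_dict()
        rmaf_results["chi2"] = chi2
        rmaf_results["p"] = pv
        if frac is not None:
            rmaf_results["expressed_fraction"] = frac.to_dict()
    except (ValueError, KeyError) as err:
        rmaf_results["note"] = f"contingency analysis skipped: {err}"
    if (muts["gene"] == "TP53").any():
        tp53_rmaf = rmaf.sample_level_rmaf(muts, "TP53", p["min_coverage"])
        rmaf_results["tp53_rmaf_n"] = int(len(tp53_rmaf))
        shared = tp53_rmaf.index.intersection(assignments.index)
        groups = assignments.loc[shared, "xi_group"]
        if groups.nunique() == 2:
            stat, pv = survival_stats.rank_tests(
                tp53_rmaf.loc[shared], groups, "wilcoxon"
            )
            med = tp53_rmaf.loc[shared].groupby(groups).median()
            rmaf_results["tp53_rmaf_by_xi"] = {
                "wilcoxon_stat": stat, "p": pv, "median": med.to_dict()
            }
    results["rmaf"] = rmaf_results

    # ---- stage 5: the four DE signatures --------------------------------
    selected = assignments.index[assignments["selected_unaltered"]]
    expr_x = cohort.expression.loc[
        [g for g in x_genes if g in cohort.expression.index]
    ]
    subtype = clinical["subtype"]

    def _contrast(case_samples, name, direction):
        case_samples = [s for s in case_samples if s not in set(selected)]
        both = list(case_samples) + list(selected)
        if len(case_samples) < 2 or len(selected) < 2:
            warnings.warn(f"contrast {name!r} skipped: too few samples")
            return None, None
        indicator = pd.Series(
            [1] * len(case_samples) + [0] * len(selected), index=both
        )
        cov = subtype.loc[both]
        if cov.nunique() < 2:
            cov = None
        try:
            de_table = de.de_analysis(expr_x, indicator, cov)
        except ValueError as err:
            warnings.warn(f"contrast {name!r} failed: {err}")
            return None, None
        sig = de.select_signature(
            de_table, direction=direction, fdr_max=p["fdr_max"], name=name
        )
        return de_table, sig

    contrasts = {
        "xi_deletion": (assignments.index[xi_del], "down"),
        "xa_amplification": (
            assignments.index[assignments["xa_group"] == xcna.XA_AMPLIFICATION],
            "up",
        ),
        "high_methylation": (
            assignments.index[assignments["methylation_group"] == "high"], "down",
        ),
        "low_methylation": (
            assignments.index[assignments["methylation_group"] == "low"], "up",
        ),
    }
    de_tables, signatures, scores, survival = {}, {}, {}, {}
    clin_t = clinical["time_years"].to_numpy(float)
    clin_e = clinical["event"].to_numpy(bool)
    for name, (case, direction) in contrasts.items():
        de_table, sig = _contrast(case, name, direction)
        if sig is None or not sig.genes:
            continue
        de_tables[name] = de_table
        signatures[name] = sig
        s = de.sig_score(cohort.expression, sig)
        scores[name] = s.loc[assignments.index]
        try:
            split = survival_stats.median_split(scores[name])
            _, lr_stat, lr_p = survival_stats.km_logrank(
                clin_t, clin_e, split, horizon_years=p["signature_horizon_years"]
            )
            cox = survival_stats.cox_hr(
                clin_t, clin_e, scores[name],
                horizon_years=p["signature_horizon_years"],
            )
            survival[name] = {
                "logrank_stat": lr_stat, "logrank_p": lr_p, "cox": cox,
                "n_genes": len(sig.genes),
            }
        except ValueError as err:
            survival[name] = {"note": f"survival evaluation skipped: {err}"}
    results["signatures"] = {
        name: {"genes": sig.genes, "provenance": sig.provenance}
        for name, sig in signatures.items()
    }
    results["survival"] = survival

    # ---- stage 6: enrichment, overlap, open chromatin -------------------
    enrich = {}
    universe = set(expr_x.index)
    tags = cohort.gene_models.set_index("gene")["region_tags"].fillna("")
    for region in ("PAR1", "PAR2", "XCU", "p53-STING"):
        region_genes = {
            g for g in universe if region in str(tags.get(g, "")).split(",")
        }
        if not region_genes:
            continue
        for name, sig in signatures.items():
            sig_in_universe = set(sig.gene_names) & universe
            if sig_in_universe:
                enrich[f"{name}__{region}"] = de.hypergeometric_enrichment(
                    sig_in_universe, region_genes, universe
                )
    results["enrichment"] = enrich

    if "xi_deletion" in signatures and "high_methylation" in signatures:
        shared, pct_a, pct_b = de.signature_overlap(
            signatures["xi_deletion"].gene_names,
            signatures["high_methylation"].gene_names,
        )
        results["overlap_xi_deletion_high_methylation"] = {
            "n_shared": len(shared),
            "pct_of_xi_deletion": pct_a,
            "pct_of_high_methylation": pct_b,
        }
    if "xa_amplification" in signatures and "low_methylation" in signatures:
        shared, pct_a, pct_b = de.signature_overlap(
            signatures["xa_amplification"].gene_names,
            signatures["low_methylation"].gene_names,
        )
        results["overlap_xa_amplification_low_methylation"] = {
            "n_shared": len(shared),
            "pct_of_xa_amplification": pct_a,
            "pct_of_low_methylation": pct_b,
        }

    if "xi_deletion" in signatures and len(selected) > 0 and len(cohort.peaks):
        try:
            flags, t_stat, t_p = de.open_chromatin_contrast(
                gene_beta[[s for s in selected if s in gene_beta.columns]],
                signatures["xi_deletion"].gene_names,
                cohort.gene_models,
                cohort.peaks,
                window_bp=p["open_chromatin_window_bp"],
            )
            results["open_chromatin"] = {
                "n_inside": int(flags.sum()),
                "n_outside": int((~flags).sum()),
                "welch_t": t_stat,
                "p": t_p,
            }
        except ValueError as err:
            results["open_chromatin"] = {"note": str(err)}

    # ---- stage 7: recovery vs planted truth (when available) ------------
    if cohort.truth is not None and len(cohort.truth):
        truth = cohort.truth.set_index("sample").loc[assignments.index]
        ari = {
            "xi": float(
                adjusted_rand_score(truth["xi_group"], assignments["xi_group"])
            )
        }
        tier2 = assignments["xa_group"] != xcna.NOT_APPLICABLE
        if tier2.any():
            ari["xa"] = float(
                adjusted_rand_score(
                    truth.loc[tier2, "xa_group"],
                    assignments.loc[tier2, "xa_group"],
                )
            )
        tier3 = assignments["methylation_group"] != xcna.NOT_APPLICABLE
        if tier3.any():
            ari["methylation"] = float(
                adjusted_rand_score(
                    truth.loc[tier3, "methylation_group"],
                    assignments.loc[tier3, "methylation_group"],
                )
            )
        results["truth_recovery_ari"] = ari

    results["_tables"] = {
        "assignments": assignments,
        "gene_beta": gene_beta,
        "mean_x_beta": mean_x_beta,
        "de_tables": de_tables,
        "scores": scores,
    }
    if outdir is not None:
        write_results(results, cohort, outdir)
    return results


def write_results(results: dict, cohort: synthdata.SyntheticCohort, outdir) -> None:
    """Persist the results tree: TSV tables, signature JSONs, survival JSON
    and a run manifest with row counts at every stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = results["_tables"]
    tables["assignments"].to_csv(outdir / "assignments.tsv", sep="\t", na_rep="NA")
    tables["gene_beta"].to_csv(outdir / "gene_beta.tsv", sep="\t", na_rep="NA")
    tables["mean_x_beta"].rename_axis("sample").to_csv(
        outdir / "mean_x_beta.tsv", sep="\t"
    )
    for name, tbl in tables["de_tables"].items():
        tbl.to_csv(outdir / f"de_{name}.tsv", sep="\t")
    if tables["scores"]:
        pd.DataFrame(tables["scores"]).rename_axis("sample").to_csv(
            outdir / "scores.tsv", sep="\t"
        )
    with open(outdir / "signatures.json", "w") as fh:
        json.dump(_json_ready(results.get("signatures", {})), fh, indent=1)
    with open(outdir / "survival.json", "w") as fh:
        json.dump(_json_ready(results.get("survival", {})), fh, indent=1)
    report = {k: v for k, v in results.items() if k != "_tables"}
    with open(outdir / "stats_report.json", "w") as fh:
        json.dump(_json_ready(report), fh, indent=1)
    cfg_dict = synthdata.config_to_dict(cohort.config)
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": cohort.config.seed,
        "n_samples": len(cohort.samples),
        "tier_sizes": results.get("tier_sizes", {}),
        "stage_rows": {
            "segments": int(len(cohort.segments)),
            "probes": int(len(cohort.probes)),
            "mutations": int(len(cohort.mutations)),
            "expression_genes": int(len(cohort.expression)),
            "assignments": int(len(tables["assignments"])),
            "signatures": {
                k: len(v["genes"]) for k, v in results.get("signatures", {}).items()
            },
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(_json_ready(manifest), fh, indent=1)


def render_report(results_dir) -> str:
    """Human-readable markdown summary of a written results tree."""
    results_dir = Path(results_dir)
    required = ["stats_report.json", "run_manifest.json"]
    missing = [f for f in required if not (results_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"results tree incomplete; missing: {missing}")
    with open(results_dir / "stats_report.json") as fh:
        report = json.load(fh)
    with open(results_dir / "run_manifest.json") as fh:
        manifest = json.load(fh)
    lines = ["# X-chromosome aberration analysis report", ""]
    lines.append(f"Samples: {manifest['n_samples']} (seed {manifest['seed']})")
    lines.append("")
    lines.append("## Cascade tier sizes")
    for k, v in report.get("tier_sizes", {}).items():
        lines.append(f"- {k}: {v}")
    if report.get("crosstabs"):
        lines.append("")
        lines.append("## Cross-tabs")
        for name, ct in report["crosstabs"].items():
            pieces = [
                f"{c} {pct}% ({n}/{d})"
                for c, pct, n, d in zip(
                    ct["categories"], ct["percent"],
                    ct["numerators"], ct["denominators"],
                )
            ]
            lines.append(f"- {name}: " + "; ".join(pieces) + f" (chi2 p={ct['p']:.3g})")
    if report.get("rmaf", {}).get("expressed_fraction"):
        lines.append("")
        lines.append("## Expressed-mutation fractions by Xi group")
        for g, f in report["rmaf"]["expressed_fraction"].items():
            lines.append(f"- {g}: {f:.3f}")
        lines.append(f"- chi-square p = {report['rmaf']['p']:.3g}")
    if report.get("signatures"):
        lines.append("")
        lines.append("## Signatures")
        for name, sig in report["signatures"].items():
            lines.append(f"- {name}: {len(sig['genes'])} genes")
    if report.get("survival"):
        lines.append("")
        lines.append("## Survival")
        for name, sv in report["survival"].items():
            if "cox" in sv:
                cox = sv["cox"]["per_unit"]
                lines.append(
                    f"- {name}: HR/unit {cox['hr']:.2f} "
                    f"[{cox['ci_low']:.2f}, {cox['ci_high']:.2f}], "
                    f"log-rank p = {sv['logrank_p']:.3g}"
                )
    if report.get("truth_recovery_ari"):
        lines.append("")
        lines.append("## Planted-truth recovery (ARI)")
        for k, v in report["truth_recovery_ari"].items():
            lines.append(f"- {k}: {v:.3f}")
    return "\n".join(lines) + "\n"
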