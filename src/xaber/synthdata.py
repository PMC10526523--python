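"""Synthetic breast-cancer cohorts with planted X-chromosome aberrations.

The generator emulates the statistical structure of a multi-omics tumour
cohort — allele-specific copy-number segments on chrX, promoter
methylation beta-values, log2 expression, somatic mutations with RNA
allele counts, and censored survival — with known per-sample ground truth,
so the full analysis cascade can be exercised and scored without any
external data.

Planted structure, per sample:

* a molecular subtype and a TP53 mutation status drawn from configured
  marginals; TP53 status then tilts the probability of the X aberration;
* Xi-large-deletion samples carry minor copy number 0 over a contiguous
  70-100% of chrX bins; Xa-large-amplification samples (drawn only among
  Xi-unaltered ones) carry major copy number 2-3 over a similar block;
  all samples get sparse focal noise;
* promoter beta-values: XCI-subject genes centre near 0.45 (one of two
  alleles methylated), pulled down in Xi-deleted and methylation-low
  samples and up in methylation-high samples; XCI escapees centre near
  0.1; genes inside synthetic open chromatin sit slightly lower;
* expression: genes in deleted bins lose, and in amplified bins gain, a
  configured log2 effect; XIST drops in Xi-deleted and TP53-mutant
  samples; methylation groups shift XCI-subject genes;
* RNA alt counts per mutation ~ Binomial(depth, p) with true expression
  fraction p in {1.0, 0.5, 0.0}; the class mix favours fully expressed
  mutations in Xi-deleted samples; TP53-mutant samples additionally carry
  a TP53 mutation whose p reflects loss of heterozygosity under CN
  aberration;
* survival: exponential (optionally Weibull) with log-hazard proportional
  to a planted aggressiveness score, under independent uniform censoring.

A single integer seed fully determines the cohort.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHRX = "chrX"

COHORT_FILES = {
    "segments": "segments.tsv",
    "methylation": "methylation.tsv",  # probe manifest + beta matrix
    "mutations": "mutations.tsv",
    "expression": "expression.tsv",
    "clinical": "clinical.tsv",
    "truth": "truth.tsv",
    "peaks": "peaks.bed",
    "gene_models": "gene_models.tsv",
}


def _default_subtype_probs():
    # TCGA-BRCA-like mix of the four most frequent subtypes
    return {"LumA": 0.54, "LumB": 0.20, "Her2": 0.08, "Basal": 0.18}


def _default_tp53_probs():
    return {"LumA": 0.12, "LumB": 0.30, "Her2": 0.70, "Basal": 0.80}


@dataclass
class SimConfig:
    """All knobs of the cohort generator; the seed fixes everything.

    Aberration rates default to the cohort-level cross-tab rates of the
    real tumour cohorts the generator emulates; effect sizes, depths and
    noise levels are generator choices (documented in the methods note).
    """

    n_samples: int = 1000
    subtype_probs: dict = field(default_factory=_default_subtype_probs)
    p_tp53_mut_by_subtype: dict = field(default_factory=_default_tp53_probs)
    p_xi_del_by_tp53: dict = field(default_factory=lambda: {"mut": 0.51, "wt": 0.18})
    p_xa_amp_by_tp53: dict = field(default_factory=lambda: {"mut": 0.68, "wt": 0.41})
    p_meth_high: float = 54.0 / 280.0
    p_meth_low: float = 25.0 / 280.0
    # chrX geometry
    n_bins: int = 100
    bin_size_bp: int = 1_000_000
    n_par_bins: int = 3  # PAR1 = first bins, PAR2 = last bins
    # gene content
    n_genes_x: int = 120
    n_genes_auto: int = 60
    p_escape: float = 0.15  # non-PAR escapee fraction
    # mutations / RMAF
    n_mutations_per_sample: float = 3.0
    rmaf_depth_mean: float = 40.0
    # expression effects (log2)
    del_logfc: float = -1.0
    amp_logfc: float = 0.8
    meth_high_logfc: float = -0.8
    meth_low_logfc: float = 0.6
    expr_noise_sd: float = 0.5
    # methylation
    beta_concentration: float = 40.0
    p_beta_missing: float = 0.02
    p_meth_missing: float = 0.0  # samples with no methylation data at all
    # survival
    signature_beta: float = math.log(3.0)
    baseline_hazard: float = 0.05  # events per year at aggressiveness 0
    survival_model: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    censor_rate: float = 0.3
    max_followup_years: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError("invalid config field n_samples: must be >= 0")
        tot = sum(self.subtype_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(
                f"invalid config field subtype_probs: probabilities sum to {tot}"
            )
        prob_fields = {
            "subtype_probs": self.subtype_probs.values(),
            "p_tp53_mut_by_subtype": self.p_tp53_mut_by_subtype.values(),
            "p_xi_del_by_tp53": self.p_xi_del_by_tp53.values(),
            "p_xa_amp_by_tp53": self.p_xa_amp_by_tp53.values(),
            "p_meth_high": [self.p_meth_high],
            "p_meth_low": [self.p_meth_low],
            "p_escape": [self.p_escape],
            "p_beta_missing": [self.p_beta_missing],
            "p_meth_missing": [self.p_meth_missing],
            "censor_rate": [self.censor_rate],
        }
        for name, vals in prob_fields.items():
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"invalid config field {name}: {v} not in [0,1]")
        for name in ("n_bins", "bin_size_bp", "n_genes_x", "n_genes_auto"):
            if getattr(self, name) < 1:
                raise ValueError(f"invalid config field {name}: must be positive")
        if self.p_meth_high + self.p_meth_low > 1.0:
            raise ValueError("invalid config field p_meth_high/p_meth_low: sum > 1")
        if self.n_mutations_per_sample < 0:
            raise ValueError("invalid config field n_mutations_per_sample: negative")
        if self.rmaf_depth_mean <= 0:
            raise ValueError("invalid config field rmaf_depth_mean: must be > 0")
        if self.survival_model not in ("exponential", "weibull"):
            raise ValueError(
                f"invalid config field survival_model: {self.survival_model!r}"
            )
        if 2 * self.n_par_bins >= self.n_bins:
            raise ValueError("invalid config field n_par_bins: PARs cover all bins")

    def marginal_xi_del(self) -> float:
        """Config-implied marginal probability of an Xi-large deletion."""
        p = 0.0
        for st, ps in self.subtype_probs.items():
            pm = self.p_tp53_mut_by_subtype[st]
            p += ps * (
                pm * self.p_xi_del_by_tp53["mut"]
                + (1 - pm) * self.p_xi_del_by_tp53["wt"]
            )
        return p


@dataclass
class SyntheticCohort:
    """All generated tables plus per-sample / per-mutation ground truth."""

    config: SimConfig
    segments: pd.DataFrame
    probes: pd.DataFrame  # probe, chromosome, position
    beta: pd.DataFrame  # probes x samples
    gene_models: pd.DataFrame  # gene, chromosome, tss, strand, region_tags
    mutations: pd.DataFrame  # incl. true_expression_p ground truth
    expression: pd.DataFrame  # genes x samples, log2
    clinical: pd.DataFrame  # sample, subtype, tp53_status, time_years, event
    peaks: pd.DataFrame  # chromosome, start, end (BED half-open)
    truth: pd.DataFrame  # per-sample planted labels

    @property
    def samples(self) -> list:
        return list(self.clinical["sample"])


def _make_gene_models(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chrom_len = cfg.n_bins * cfg.bin_size_bp
    tss = np.sort(rng.integers(1, chrom_len + 1, size=cfg.n_genes_x))
    genes = [f"XG{i:04d}" for i in range(cfg.n_genes_x)]
    strand = rng.choice(["+", "-"], size=cfg.n_genes_x)
    bin_idx = (tss - 1) // cfg.bin_size_bp
    par1 = bin_idx < cfg.n_par_bins
    par2 = bin_idx >= cfg.n_bins - cfg.n_par_bins
    escape = par1 | par2 | (rng.random(cfg.n_genes_x) < cfg.p_escape)

    # XIST near the middle of the chromosome; treated as an escapee-like
    # promoter (it is expressed from the Xi)
    xist_pos = chrom_len // 2 + 12345
    tags = []
    for i in range(cfg.n_genes_x):
        t = []
        if par1[i]:
            t.append("PAR1")
        if par2[i]:
            t.append("PAR2")
        tags.append(t)
    for tag, n_tag in (("XCU", 20), ("p53-STING", 15), ("COSMIC-TS", 5)):
        chosen = rng.choice(cfg.n_genes_x, size=min(n_tag, cfg.n_genes_x), replace=False)
        for i in chosen:
            tags[i].append(tag)
    x = pd.DataFrame(
        {
            "gene": genes,
            "chromosome": CHRX,
            "tss": tss,
            "strand": strand,
            "region_tags": [",".join(t) for t in tags],
            "escapes_xci": escape,
        }
    )
    xist = pd.DataFrame(
        {
            "gene": ["XIST"],
            "chromosome": [CHRX],
            "tss": [xist_pos],
            "strand": ["-"],
            "region_tags": [""],
            "escapes_xci": [True],
        }
    )
    auto = pd.DataFrame(
        {
            "gene": ["TP53"] + [f"AG{i:04d}" for i in range(cfg.n_genes_auto)],
            "chromosome": ["chr17"] + ["chr1"] * cfg.n_genes_auto,
            "tss": np.concatenate(
                [[7_571_720], rng.integers(1, 200_000_000, size=cfg.n_genes_auto)]
            ),
            "strand": rng.choice(["+", "-"], size=cfg.n_genes_auto + 1),
            "region_tags": "",
            "escapes_xci": False,
        }
    )
    return pd.concat([x, xist, auto], ignore_index=True)


def _segments_from_bins(
    sample: str, minor: np.ndarray, major: np.ndarray, cfg: SimConfig
) -> list:
    """Run-length encode per-bin (minor, major) into segment rows."""
    rows = []
    start_bin = 0
    for b in range(1, cfg.n_bins + 1):
        if b == cfg.n_bins or minor[b] != minor[start_bin] or major[b] != major[start_bin]:
            rows.append(
                (
                    sample,
                    CHRX,
                    start_bin * cfg.bin_size_bp + 1,
                    b * cfg.bin_size_bp,
                    int(major[start_bin]),
                    int(minor[start_bin]),
                )
            )
            start_bin = b
    return rows


def simulate_survival(
    aggressiveness: np.ndarray, cfg: SimConfig, rng: np.random.Generator
):
    """Event/censoring times for a vector of aggressiveness scores.

    Hazard = baseline_hazard * exp(signature_beta * score); exponential by
    default, Weibull via ``survival_model='weibull'``.  Censoring combines
    an administrative cut at ``max_followup_years`` with, for a
    ``censor_rate`` fraction of samples, an independent Uniform(0, max)
    drop-out time.  Returns (time, event).
    """
    a = np.asarray(aggressiveness, dtype=float)
    hazard = cfg.baseline_hazard * np.exp(cfg.signature_beta * a)
    u = rng.random(a.shape)
    if cfg.survival_model == "weibull":
        t_event = (-np.log(u) / hazard) ** (1.0 / cfg.weibull_shape)
    else:
        t_event = -np.log(u) / hazard
    censor = np.full(a.shape, cfg.max_followup_years)
    dropout = rng.random(a.shape) < cfg.censor_rate
    censor[dropout] = rng.uniform(0, cfg.max_followup_years, size=a.shape)[dropout]
    time = np.minimum(t_event, censor)
    event = t_event <= censor
    return time, event


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one complete synthetic cohort from a validated configuration."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    # --- clinical skeleton: subtype, TP53, planted aberration tier -------
    subtype_names = list(cfg.subtype_probs)
    subtypes = rng.choice(subtype_names, size=n, p=list(cfg.subtype_probs.values()))
    p_mut = np.array([cfg.p_tp53_mut_by_subtype[s] for s in subtypes])
    tp53 = np.where(rng.random(n) < p_mut, "mut", "wt")
    p_del = np.array([cfg.p_xi_del_by_tp53[t] for t in tp53])
    xi_del = rng.random(n) < p_del
    p_amp = np.array([cfg.p_xa_amp_by_tp53[t] for t in tp53])
    xa_amp = (~xi_del) & (rng.random(n) < p_amp)
    meth_group = np.full(n, "unaltered", dtype=object)
    cn_quiet = ~(xi_del | xa_amp)
    draw = rng.random(n)
    meth_group[cn_quiet & (draw < cfg.p_meth_high)] = "high"
    meth_group[
        cn_quiet & (draw >= cfg.p_meth_high) & (draw < cfg.p_meth_high + cfg.p_meth_low)
    ] = "low"
    meth_group[~cn_quiet] = "cn-altered"

    # --- per-bin copy number and segments --------------------------------
    minor_bins = np.ones((n, cfg.n_bins), dtype=np.int64)
    major_bins = np.ones((n, cfg.n_bins), dtype=np.int64)
    seg_rows = []
    for i in range(n):
        if xi_del[i]:
            f = rng.uniform(0.7, 1.0)
            width = max(1, int(round(f * cfg.n_bins)))
            start = int(rng.integers(0, cfg.n_bins - width + 1))
            minor_bins[i, start : start + width] = 0
        elif xa_amp[i]:
            f = rng.uniform(0.7, 1.0)
            width = max(1, int(round(f * cfg.n_bins)))
            start = int(rng.integers(0, cfg.n_bins - width + 1))
            # amplified level varies along the block in chunks of 2 or 3
            # copies (stepwise segments, as real amplifications show)
            pos = start
            while pos < start + width:
                chunk = min(int(rng.integers(5, 20)), start + width - pos)
                major_bins[i, pos : pos + chunk] = int(rng.choice([2, 3]))
                pos += chunk
        # sparse focal noise everywhere
        for _ in range(rng.poisson(0.5)):
            w = int(rng.integers(1, 4))
            pos = int(rng.integers(0, cfg.n_bins - w + 1))
            if rng.random() < 0.5:
                minor_bins[i, pos : pos + w] = 0
            else:
                major_bins[i, pos : pos + w] = np.maximum(
                    major_bins[i, pos : pos + w], 2
                )
        seg_rows.extend(
            _segments_from_bins(samples[i], minor_bins[i], major_bins[i], cfg)
        )
    segments = pd.DataFrame(
        seg_rows,
        columns=["sample", "chromosome", "start", "end", "major_cn", "minor_cn"],
    )

    # --- gene models, probes, open chromatin ------------------------------
    gene_models = _make_gene_models(cfg, rng)
    x_mask = (gene_models["chromosome"] == CHRX).to_numpy()
    x_models = gene_models[x_mask].reset_index(drop=True)
    n_x = len(x_models)
    x_bin = ((x_models["tss"].to_numpy() - 1) // cfg.bin_size_bp).astype(int)
    escape = x_models["escapes_xci"].to_numpy()

    open_chrom = np.where(
        escape, rng.random(n_x) < 0.8, rng.random(n_x) < 0.35
    )
    peak_rows = [
        (CHRX, int(t) - 501, int(t) + 500)
        for t, f in zip(x_models["tss"], open_chrom)
        if f
    ]
    # a few intergenic peaks for realism
    for pos in rng.integers(1, cfg.n_bins * cfg.bin_size_bp, size=10):
        peak_rows.append((CHRX, int(pos), int(pos) + 800))
    peaks = pd.DataFrame(peak_rows, columns=["chromosome", "start", "end"])
    peaks = peaks.sort_values(["start", "end"]).reset_index(drop=True)

    probe_rows = []
    probe_gene = []  # parallel: which X gene row each probe belongs to (-1 orphan)
    pid = 0
    for gi, tss in enumerate(x_models["tss"]):
        if rng.random() < 0.15:  # far-only gene: probes in the 200-1500 ring
            k = int(rng.integers(1, 3))
            offs = rng.integers(201, 1501, size=k) * rng.choice([-1, 1], size=k)
        else:
            k = 1 + int(rng.poisson(1.0))
            offs = rng.integers(-200, 201, size=k)
        for off in offs:
            probe_rows.append((f"cg{pid:07d}", CHRX, max(1, int(tss) + int(off))))
            probe_gene.append(gi)
            pid += 1
    for pos in rng.integers(1, cfg.n_bins * cfg.bin_size_bp, size=15):  # orphans
        probe_rows.append((f"cg{pid:07d}", CHRX, int(pos)))
        probe_gene.append(-1)
        pid += 1
    probes = pd.DataFrame(probe_rows, columns=["probe", "chromosome", "position"])
    probe_gene = np.asarray(probe_gene)

    # --- beta values -------------------------------------------------------
    # per-gene baseline mean with a small between-gene jitter
    gene_base = np.where(escape, 0.10, np.where(open_chrom, 0.36, 0.47))
    gene_base = np.clip(gene_base + rng.normal(0, 0.03, size=n_x), 0.02, 0.95)
    meth_missing = rng.random(n) < cfg.p_meth_missing
    gene_mean = np.tile(gene_base[:, None], (1, n))  # genes x samples
    subject = ~escape
    gene_mean[np.ix_(subject, xi_del)] = 0.15
    gene_mean[np.ix_(subject, meth_group == "low")] = 0.15
    gene_mean[np.ix_(subject, meth_group == "high")] = 0.80
    c = cfg.beta_concentration
    beta_genes = rng.beta(gene_mean * c, (1 - gene_mean) * c)
    beta_vals = np.full((len(probes), n), np.nan)
    has_gene = probe_gene >= 0
    # probe value = gene-level draw plus probe-level noise, clipped to [0,1]
    beta_vals[has_gene] = np.clip(
        beta_genes[probe_gene[has_gene]]
        + rng.normal(0, 0.03, size=(has_gene.sum(), n)),
        0.0,
        1.0,
    )
    beta_vals[~has_gene] = np.clip(
        rng.beta(0.45 * c, 0.55 * c, size=((~has_gene).sum(), n)), 0, 1
    )
    miss = rng.random(beta_vals.shape) < cfg.p_beta_missing
    beta_vals[miss] = np.nan
    beta_vals[:, meth_missing] = np.nan
    beta = pd.DataFrame(
        beta_vals, index=pd.Index(probes["probe"], name="probe"), columns=samples
    )

    # --- expression --------------------------------------------------------
    all_genes = list(gene_models["gene"])
    baseline = rng.normal(8.0, 1.5, size=len(all_genes))
    expr = np.tile(baseline[:, None], (1, n)) + rng.normal(
        0, cfg.expr_noise_sd, size=(len(all_genes), n)
    )
    expr_df = pd.DataFrame(
        expr, index=pd.Index(all_genes, name="gene"), columns=samples
    )
    x_gene_names = list(x_models["gene"])
    deleted = minor_bins[:, x_bin].T < 0.5  # genes x samples
    amplified = major_bins[:, x_bin].T > 1.5
    expr_df.loc[x_gene_names] += deleted * cfg.del_logfc + amplified * cfg.amp_logfc
    subj_names = [g for g, s in zip(x_gene_names, subject) if s]
    expr_df.loc[subj_names, meth_group == "high"] += cfg.meth_high_logfc
    expr_df.loc[subj_names, meth_group == "low"] += cfg.meth_low_logfc
    expr_df.loc["XIST"] = (
        10.0 + rng.normal(0, cfg.expr_noise_sd, size=n)
        - 2.0 * xi_del
        - 1.0 * (tp53 == "mut")
    )

    # --- somatic mutations with RNA allele counts --------------------------
    mut_rows = []
    class_choices = np.array(["Missense", "Nonsense", "Splice_Site", "Silent"])
    class_p = [0.6, 0.1, 0.1, 0.2]
    for i in range(n):
        n_mut = rng.poisson(cfg.n_mutations_per_sample)
        for _ in range(n_mut):
            gi = int(rng.integers(0, n_x))
            if xi_del[i]:
                true_p = float(rng.choice([1.0, 0.5, 0.0], p=[0.8, 0.1, 0.1]))
            else:
                true_p = float(rng.choice([1.0, 0.5, 0.0], p=[0.4, 0.25, 0.35]))
            depth = int(rng.poisson(cfg.rmaf_depth_mean))
            alt = int(rng.binomial(depth, true_p)) if depth else 0
            mut_rows.append(
                (
                    samples[i],
                    x_models["gene"].iloc[gi],
                    CHRX,
                    int(x_models["tss"].iloc[gi]) + int(rng.integers(0, 5000)),
                    str(rng.choice(class_choices, p=class_p)),
                    depth - alt,
                    alt,
                    true_p,
                )
            )
        if tp53[i] == "mut":
            true_p = 0.95 if (xi_del[i] or xa_amp[i]) else 0.5
            depth = int(rng.poisson(cfg.rmaf_depth_mean))
            alt = int(rng.binomial(depth, true_p)) if depth else 0
            mut_rows.append(
                (
                    samples[i], "TP53", "chr17",
                    7_577_121, "Missense", depth - alt, alt, true_p,
                )
            )
    mutations = pd.DataFrame(
        mut_rows,
        columns=[
            "sample", "gene", "chromosome", "position",
            "classification", "ref_count", "alt_count", "true_expression_p",
        ],
    )

    # --- survival -----------------------------------------------------------
    aggressiveness = (
        1.0 * xi_del
        + 0.7 * xa_amp
        + 0.5 * (meth_group == "high")
        + 0.4 * (meth_group == "low")
        + 0.2 * (tp53 == "mut")
    )
    time, event = simulate_survival(aggressiveness, cfg, rng)
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "subtype": subtypes,
            "tp53_status": tp53,
            "time_years": np.round(time, 4),
            "event": event.astype(int),
        }
    )
    truth = pd.DataFrame(
        {
            "sample": samples,
            "xi_group": np.where(xi_del, "Xi-large-deletion", "Xi-unaltered"),
            "xa_group": np.where(
                xi_del, "not-applicable",
                np.where(xa_amp, "Xa-large-amplification", "Xa-unaltered"),
            ),
            "methylation_group": np.where(
                ~cn_quiet, "not-applicable", meth_group
            ),
            "has_methylation": ~meth_missing,
            "aggressiveness": aggressiveness,
        }
    )
    return SyntheticCohort(
        config=cfg,
        segments=segments,
        probes=probes,
        beta=beta,
        gene_models=gene_models.drop(columns=["escapes_xci"]),
        mutations=mutations,
        expression=expr_df.round(5),
        clinical=clinical,
        peaks=peaks,
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write every cohort table as TSV/BED; returns {filename: n_rows}.

    The probe manifest and beta matrix are combined in one table
    (probe, chromosome, position, then one column per sample).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meth = cohort.probes.set_index("probe").join(cohort.beta)
    tables = {
        COHORT_FILES["segments"]: cohort.segments,
        COHORT_FILES["methylation"]: meth.reset_index(),
        COHORT_FILES["mutations"]: cohort.mutations,
        COHORT_FILES["expression"]: cohort.expression.reset_index(),
        COHORT_FILES["clinical"]: cohort.clinical,
        COHORT_FILES["truth"]: cohort.truth,
        COHORT_FILES["gene_models"]: cohort.gene_models,
    }
    manifest = {}
    try:
        for fname, df in tables.items():
            df.to_csv(directory / fname, sep="\t", index=False, na_rep="NA")
            manifest[fname] = int(len(df))
        cohort.peaks.to_csv(
            directory / COHORT_FILES["peaks"], sep="\t", index=False, header=False
        )
        manifest[COHORT_FILES["peaks"]] = int(len(cohort.peaks))
    except OSError as err:
        raise OSError(f"failed writing cohort to {directory}: {err}") from err
    pd.Series(manifest, name="rows").rename_axis("file").to_csv(
        directory / "manifest.tsv", sep="\t"
    )
    return manifest


def read_cohort(directory, config: SimConfig | None = None) -> SyntheticCohort:
    """Round-trip loader for a directory written by :func:`write_cohort`."""
    directory = Path(directory)

    def _read(fname, **kw):
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing cohort file: {path}")
        kw.setdefault("na_values", ["NA"])
        return pd.read_csv(path, sep="\t", **kw)

    meth = _read(COHORT_FILES["methylation"])
    probes = meth[["probe", "chromosome", "position"]].copy()
    beta = meth.drop(columns=["chromosome", "position"]).set_index("probe")
    beta.columns.name = None
    expression = _read(COHORT_FILES["expression"]).set_index("gene")
    clinical = _read(COHORT_FILES["clinical"])
    peaks_path = directory / COHORT_FILES["peaks"]
    if peaks_path.stat().st_size > 0:
        peaks = pd.read_csv(
            peaks_path, sep="\t", header=None, names=["chromosome", "start", "end"]
        )
    else:
        peaks = pd.DataFrame(columns=["chromosome", "start", "end"])
    gene_models = _read(COHORT_FILES["gene_models"], keep_default_na=False,
                        na_values=[]).replace({"region_tags": {"": ""}})
    gene_models["tss"] = gene_models["tss"].astype(np.int64)
    return SyntheticCohort(
        config=config if config is not None else SimConfig(),
        segments=_read(COHORT_FILES["segments"]),
        probes=probes,
        beta=beta,
        gene_models=gene_models,
        mutations=_read(COHORT_FILES["mutations"]),
        expression=expression,
        clinical=clinical,
        peaks=peaks,
        truth=_read(COHORT_FILES["truth"]),
    )


def config_to_dict(cfg: SimConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> SimConfig:
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
    return SimConfig(**d)
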