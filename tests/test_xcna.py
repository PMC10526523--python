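"""Copy-number binning, Gower dissimilarity, Ward clustering, cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from xaber import xcna


def seg(sample, start, end, major, minor, chrom="chrX"):
    return {
        "sample": sample, "chromosome": chrom, "start": start, "end": end,
        "major_cn": major, "minor_cn": minor,
    }


def brute_force_bin(segments, bins, cn_col):
    """Interval-arithmetic oracle: per (sample, bin) loop over segments."""
    out = {}
    for sample, sub in segments.groupby("sample"):
        row = []
        for _, b in bins.iterrows():
            num = den = 0.0
            for _, s in sub.iterrows():
                lo, hi = max(b["start"], s["start"]), min(b["end"], s["end"])
                if hi >= lo:
                    num += (hi - lo + 1) * s[cn_col]
                    den += hi - lo + 1
            row.append(num / den if den else np.nan)
        out[sample] = row
    return pd.DataFrame(out).T


def brute_force_gower(X):
    X = np.asarray(X, float)
    rngs = X.max(axis=0) - X.min(axis=0)
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            vals = [
                abs(X[i, k] - X[j, k]) / rngs[k]
                for k in range(X.shape[1])
                if rngs[k] > 0
            ]
            D[i, j] = np.mean(vals)
    return D


class TestBinSegments:
    def test_full_deletion_gives_zero_row(self):
        bins = xcna.make_bins(5, 100)
        segs = pd.DataFrame([seg("a", 1, 500, 1, 0)])
        out = xcna.bin_segments(segs, bins, "minor")
        assert (out.values.loc["a"] == 0).all()
        assert not out.uncovered.loc["a"].any()

    def test_length_weighted_mean_within_bin(self):
        bins = xcna.make_bins(1, 100)
        segs = pd.DataFrame([seg("a", 1, 50, 1, 0), seg("a", 51, 100, 1, 1)])
        out = xcna.bin_segments(segs, bins, "minor")
        assert out.values.loc["a", 0] == pytest.approx(0.5)

    def test_matches_interval_arithmetic_oracle(self, rng):
        bins = xcna.make_bins(5, 1000)
        rows = []
        for sample in ["s1", "s2", "s3"]:
            pos = 1
            while pos < 5000:
                end = min(5000, pos + int(rng.integers(300, 2500)))
                rows.append(seg(sample, pos, end, int(rng.integers(1, 4)),
                                int(rng.integers(0, 2))))
                pos = end + 1
        segs = pd.DataFrame(rows)
        for allele in ("minor", "major"):
            out = xcna.bin_segments(segs, bins, allele)
            oracle = brute_force_bin(segs, bins, f"{allele}_cn")
            np.testing.assert_allclose(
                out.values.to_numpy(), oracle.loc[out.values.index].to_numpy(),
                atol=1e-12,
            )

    def test_uncovered_bins_take_modal_value_and_flag(self):
        bins = xcna.make_bins(4, 100)
        segs = pd.DataFrame([seg("a", 1, 100, 1, 1), seg("a", 101, 200, 1, 1),
                             seg("a", 201, 300, 3, 0)])
        out = xcna.bin_segments(segs, bins, "major")
        assert out.uncovered.loc["a", 3]
        assert out.values.loc["a", 3] == 1  # modal by covered length

    def test_overlapping_segments_rejected(self):
        bins = xcna.make_bins(2, 100)
        segs = pd.DataFrame([seg("a", 1, 120, 1, 1), seg("a", 100, 200, 2, 1)])
        with pytest.raises(ValueError, match="overlap"):
            xcna.bin_segments(segs, bins, "minor")

    def test_mass_conservation_on_fully_covered_chromosome(self, rng):
        """Length-weighted mean over bins equals that over segments."""
        bins = xcna.make_bins(10, 500)
        rows, pos = [], 1
        while pos <= 5000:
            end = min(5000, pos + int(rng.integers(100, 1500)))
            rows.append(seg("a", pos, end, int(rng.integers(1, 4)), 1))
            pos = end + 1
        segs = pd.DataFrame(rows)
        out = xcna.bin_segments(segs, bins, "major")
        lengths = segs["end"] - segs["start"] + 1
        seg_mean = float((lengths * segs["major_cn"]).sum() / lengths.sum())
        assert out.values.loc["a"].mean() == pytest.approx(seg_mean, abs=1e-9)


class TestGower:
    def test_identical_rows_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (3, 1))
        X[2, 0] = 5.0  # keep one column with range
        D = xcna.gower_dissimilarity(X)
        assert D[0, 1] == 0.0

    def test_min_max_pair_is_one(self):
        D = xcna.gower_dissimilarity(np.array([[0.0], [10.0]]))
        assert D[0, 1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.random((4, 3))
        np.testing.assert_allclose(
            xcna.gower_dissimilarity(X), brute_force_gower(X), atol=1e-12
        )

    def test_all_constant_columns_rejected(self):
        with pytest.raises(ValueError, match="zero range"):
            xcna.gower_dissimilarity(np.ones((3, 4)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arrays(
            float, (5, 4),
            elements=st.floats(0, 10, allow_nan=False, width=32),
        ).filter(lambda X: (X.max(axis=0) - X.min(axis=0) > 0).any())
    )
    def test_symmetry_bounds_zero_diagonal(self, X):
        D = xcna.gower_dissimilarity(X)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.allclose(np.diag(D), 0)
        assert (D >= -1e-12).all() and (D <= 1 + 1e-12).all()

    def test_missing_values_skipped_pairwise(self):
        X = np.array([[0.0, 0.0], [np.nan, 1.0], [1.0, 0.5]])
        D = xcna.gower_dissimilarity(X)
        # pair (0,1) can only use column 2
        assert D[0, 1] == pytest.approx(1.0)


class TestWard:
    def test_separated_clouds(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (12, 3))])
        labels = xcna.ward_cluster(xcna.gower_dissimilarity(X), 2)
        truth = [0] * 10 + [1] * 12
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self, rng):
        X = rng.random((6, 2))
        labels = xcna.ward_cluster(xcna.gower_dissimilarity(X), 6)
        assert len(set(labels)) == 6

    def test_asymmetric_input_rejected(self):
        D = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            xcna.ward_cluster(D, 2)


class TestXiXaGroups:
    def test_pure_deletion_cohort_exact_recovery(self):
        M = pd.DataFrame(
            np.vstack([np.zeros((5, 10)), np.ones((7, 10))]),
            index=[f"s{i}" for i in range(12)],
        )
        out = xcna.assign_xi_groups(M)
        assert (out.iloc[:5] == xcna.XI_DELETION).all()
        assert (out.iloc[5:] == xcna.XI_UNALTERED).all()

    def test_identical_samples_collapse_to_unaltered(self):
        M = pd.DataFrame(np.ones((4, 6)))
        with pytest.warns(UserWarning, match="identical"):
            out = xcna.assign_xi_groups(M)
        assert (out == xcna.XI_UNALTERED).all()

    def test_pure_amplification_exact_recovery(self):
        M = pd.DataFrame(
            np.vstack([np.full((4, 8), 3.0), np.ones((6, 8))]),
            index=[f"s{i}" for i in range(10)],
        )
        out = xcna.assign_xa_groups(M)
        assert (out.iloc[:4] == xcna.XA_AMPLIFICATION).all()
        assert (out.iloc[4:] == xcna.XA_UNALTERED).all()

    def test_empty_xa_input_gives_empty_output(self):
        out = xcna.assign_xa_groups(pd.DataFrame(columns=range(5)))
        assert len(out) == 0

    def test_planted_cohort_recovery(self, small_cohort, small_bins):
        minor = xcna.bin_segments(small_cohort.segments, small_bins, "minor")
        out = xcna.assign_xi_groups(minor.values)
        truth = small_cohort.truth.set_index("sample").loc[out.index, "xi_group"]
        assert adjusted_rand_score(truth, out) >= 0.95
        # recovered deletion fraction within 3 binomial SE of planted marginal
        p = small_cohort.config.marginal_xi_del()
        n = len(out)
        frac = (out == xcna.XI_DELETION).mean()
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestCascade:
    def test_nested_tiers_and_partition(self, small_cohort, small_bins):
        res = xcna.run_cascade(small_cohort.segments, small_bins)
        a = res.assignments
        # xa applicable only within Xi-unaltered; meth only within Xa-unaltered
        assert (
            (a["xa_group"] != xcna.NOT_APPLICABLE)
            == (a["xi_group"] == xcna.XI_UNALTERED)
        ).all()
        assert res.tier_sizes["xi_unaltered"] == (
            a["xi_group"] == xcna.XI_UNALTERED
        ).sum()
        # without methylation data nothing reaches tier 3
        assert (a["methylation_group"] == xcna.NOT_APPLICABLE).all()
        assert not a["selected_unaltered"].any()

    def test_all_unaltered_cohort_everyone_selected(self):
        rows = [seg(f"s{i}", 1, 1000, 1, 1) for i in range(6)]
        bins = xcna.make_bins(10, 100)
        gene_beta = pd.DataFrame(
            0.45 * np.ones((3, 6)), index=["G1", "G2", "G3"],
            columns=[f"s{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning):
            res = xcna.run_cascade(pd.DataFrame(rows), bins, gene_beta_x=gene_beta)
        assert res.assignments["selected_unaltered"].all()

    def test_sample_without_methylation_gets_not_applicable(
        self, small_cohort, small_bins
    ):
        from xaber import methylation, pipeline

        mapping = methylation.assign_probes_to_genes(
            small_cohort.probes, small_cohort.gene_models
        )
        gene_beta = methylation.gene_promoter_beta(small_cohort.beta, mapping)
        dropped = gene_beta.columns[0]
        res = xcna.run_cascade(
            small_cohort.segments, small_bins,
            gene_beta_x=gene_beta.drop(columns=[dropped]),
        )
        a = res.assignments
        assert a.loc[dropped, "methylation_group"] == xcna.NOT_APPLICABLE
        assert a.loc[dropped, "xi_group"] in (xcna.XI_DELETION, xcna.XI_UNALTERED)
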