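"""Differential expression, variance moderation, signatures and scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xaber import de_signatures as de


def two_group_expression(rng, n_genes=20, n_per_arm=10, delta=0.0, sd=1.0):
    samples = [f"a{i}" for i in range(n_per_arm)] + [f"b{i}" for i in range(n_per_arm)]
    X = rng.normal(5, sd, size=(n_genes, 2 * n_per_arm))
    X[:, n_per_arm:] += delta
    expr = pd.DataFrame(X, index=[f"G{i}" for i in range(n_genes)], columns=samples)
    group = pd.Series([0] * n_per_arm + [1] * n_per_arm, index=samples)
    return expr, group


class TestFitGeneModels:
    def test_no_covariate_logfc_is_mean_difference(self, rng):
        expr, group = two_group_expression(rng, n_genes=5, delta=2.0, sd=1e-9)
        fits = de.fit_gene_models(expr, group)
        np.testing.assert_allclose(fits["logFC"], 2.0, atol=1e-6)

    def test_confounded_covariate_rejected(self):
        expr, group = two_group_expression(np.random.default_rng(0), n_genes=3)
        subtype = pd.Series(
            np.where(group == 1, "Basal", "LumA"), index=group.index
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            de.fit_gene_models(expr, group, subtype)

    def test_planted_logfc_recovered(self, rng):
        expr, group = two_group_expression(
            rng, n_genes=300, n_per_arm=50, delta=1.0, sd=0.5
        )
        fits = de.fit_gene_models(expr, group)
        assert abs(fits["logFC"].mean() - 1.0) < 0.1

    def test_covariate_adjustment_removes_subtype_bias(self, rng):
        """A subtype that is over-represented in the case arm and shifts
        expression must not leak into the group coefficient."""
        expr, group = two_group_expression(rng, n_genes=100, n_per_arm=40, sd=0.5)
        subtype = pd.Series("LumA", index=group.index)
        # 75% of cases but only 25% of controls are Basal; Basal adds +1
        basal = np.r_[rng.random(40) < 0.25, rng.random(40) < 0.75]
        subtype[basal] = "Basal"
        expr.loc[:, basal] += 1.0
        unadj = de.fit_gene_models(expr, group)
        adj = de.fit_gene_models(expr, group, subtype)
        assert abs(unadj["logFC"].mean()) > 0.3  # biased without the covariate
        assert abs(adj["logFC"].mean()) < 0.1


class TestModerateVariances:
    def test_equal_variances_no_shrinkage_target_change(self):
        s2 = np.full(50, 2.0)
        res = de.moderate_variances(s2, df=10)
        np.testing.assert_allclose(res.posterior_var, 2.0, rtol=1e-6)

    def test_zero_prior_df_reduces_to_ordinary_t(self, rng):
        expr, group = two_group_expression(rng, n_genes=30, n_per_arm=8)
        fits = de.fit_gene_models(expr, group)
        mod = de.ModerationResult(
            prior_df=0.0, prior_var=1.0, posterior_var=fits["sigma2"].to_numpy()
        )
        table = de.moderated_t_table(fits, mod)
        ordinary_t = fits["logFC"] / fits["se"]
        np.testing.assert_allclose(table["t_mod"], ordinary_t, rtol=1e-10)

    def test_infinite_prior_df_pools_to_prior_variance(self, rng):
        s2 = np.exp(rng.normal(0, 1, size=200))
        res = de.moderate_variances(s2, df=4)
        big = (res.prior_df * res.prior_var + 4 * s2) / (res.prior_df + 4)
        if math.isinf(res.prior_df):
            np.testing.assert_allclose(res.posterior_var, res.prior_var)
        else:
            np.testing.assert_allclose(res.posterior_var, big)

    def test_known_prior_recovered(self, rng):
        """Variances drawn from a scaled inverse-chi-square prior with
        d0=4, s0^2=1: the moment fit recovers d0 within 25% and s0^2
        within 10% at 2000 genes."""
        d0, s02, df = 4.0, 1.0, 16
        sigma2 = s02 * d0 / rng.chisquare(d0, size=2000)
        s2 = sigma2 * rng.chisquare(df, size=2000) / df
        res = de.moderate_variances(s2, df=df)
        assert abs(res.prior_df - d0) / d0 < 0.25
        assert abs(res.prior_var - s02) / s02 < 0.10

    def test_nonpositive_variances_rejected(self):
        with pytest.raises(ValueError):
            de.moderate_variances(np.r_[np.ones(20), 0.0], df=5)


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            de.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert de.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_step_up(self, rng):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        p = rng.random(37)
        np.testing.assert_allclose(de.bh_fdr(p), oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.1, 1.2])

    def test_fdr_dominates_p_and_is_monotone(self, rng):
        p = rng.random(100)
        fdr = de.bh_fdr(p)
        assert (fdr >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestSelectSignature:
    def make_results(self):
        return pd.DataFrame(
            {
                "logFC": [-1.0, 1.0, -2.0, 0.0, -0.5],
                "fdr": [0.04, 0.04, 0.2, 0.01, 0.01],
            },
            index=["A", "B", "C", "D", "E"],
        )

    def test_down_direction_rules(self):
        sig = de.select_signature(self.make_results(), "down")
        assert sig.genes == [("A", -1), ("E", -1)]

    def test_up_down_disjoint(self):
        res = self.make_results()
        down = set(de.select_signature(res, "down").gene_names)
        up = set(de.select_signature(res, "up").gene_names)
        assert not down & up

    def test_zero_logfc_excluded_both_ways(self):
        res = self.make_results()
        for direction in ("down", "up"):
            assert "D" not in de.select_signature(res, direction).gene_names

    def test_empty_selection_warns(self):
        res = pd.DataFrame({"logFC": [1.0], "fdr": [0.9]}, index=["A"])
        with pytest.warns(UserWarning, match="empty"):
            sig = de.select_signature(res, "down")
        assert sig.genes == []


class TestSigScore:
    def quantile_fixture(self, rng):
        X = rng.normal(0, 1, size=(3, 200))
        return pd.DataFrame(X, index=["A", "B", "C"],
                            columns=[f"s{i}" for i in range(200)])

    def test_sample_at_upper_quantiles_scores_one(self, rng):
        expr = self.quantile_fixture(rng)
        hi = expr.quantile(0.975, axis=1)
        expr["top"] = hi + 1  # beyond the clipping quantile on every gene
        sig = de.Signature("s", [("A", 1), ("B", 1), ("C", 1)])
        assert de.sig_score(expr, sig)["top"] == pytest.approx(1.0)

    def test_negating_weights_negates_scores(self, rng):
        expr = self.quantile_fixture(rng)
        pos = de.Signature("p", [("A", 1), ("B", -1)])
        neg = de.Signature("n", [("A", -1), ("B", 1)])
        np.testing.assert_allclose(
            de.sig_score(expr, pos), -de.sig_score(expr, neg), atol=1e-12
        )

    def test_worked_three_gene_fixture(self):
        # 1 sample of interest amid anchors that pin the 2.5/97.5% quantiles
        cols = {f"pad{i}": [0.0, 0.0, 0.0] for i in range(40)}
        cols.update({f"cap{i}": [10.0, 10.0, 10.0] for i in range(40)})
        cols["x"] = [5.0, 2.5, 7.5]
        expr = pd.DataFrame(cols, index=["A", "B", "C"])
        sig = de.Signature("s", [("A", 1), ("B", 1), ("C", -1)])
        lo = expr.quantile(0.025, axis=1)
        hi = expr.quantile(0.975, axis=1)
        rescaled = ((expr["x"] - lo) / (hi - lo)).clip(0, 1) * 2 - 1
        expected = (rescaled["A"] + rescaled["B"] - rescaled["C"]) / 3
        assert de.sig_score(expr, sig)["x"] == pytest.approx(expected)

    def test_gene_order_and_absent_gene_invariance(self, rng):
        expr = self.quantile_fixture(rng)
        sig = de.Signature("s", [("A", 1), ("C", -1)])
        shuffled = de.Signature("s", [("C", -1), ("A", 1)])
        with_ghost = de.Signature("s", [("A", 1), ("C", -1), ("ZZ", 1)])
        base = de.sig_score(expr, sig)
        np.testing.assert_allclose(base, de.sig_score(expr, shuffled))
        with pytest.warns(UserWarning, match="absent"):
            ghost = de.sig_score(expr, with_ghost)
        np.testing.assert_allclose(base, ghost)

    def test_no_usable_genes_rejected(self, rng):
        expr = self.quantile_fixture(rng)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                de.sig_score(expr, de.Signature("s", [("ZZ", 1)]))


class TestHypergeometric:
    def test_closed_form_example(self):
        # universe 10, region 5, signature 4, overlap 4:
        # P = C(5,4) C(5,0) / C(10,4) = 5/210
        universe = [f"g{i}" for i in range(10)]
        region = universe[:5]
        sig = universe[:4]
        p = de.hypergeometric_enrichment(sig, region, universe)
        assert p == pytest.approx(5 / 210)

    def test_zero_overlap_and_full_signature(self):
        universe = [f"g{i}" for i in range(10)]
        assert de.hypergeometric_enrichment(
            universe[5:7], universe[:5], universe
        ) == pytest.approx(
            stats.hypergeom.sf(-1, 10, 5, 2)
        ) == pytest.approx(1.0)
        assert de.hypergeometric_enrichment(
            universe, universe[:5], universe
        ) == pytest.approx(1.0)

    def test_subset_preconditions(self):
        with pytest.raises(ValueError):
            de.hypergeometric_enrichment(["zz"], ["g0"], ["g0", "g1"])


class TestSignatureOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, ({"b", "c"}, 67, 67)),
            ({"a"}, {"b"}, (set(), 0, 0)),
        ],
    )
    def test_shared_and_percent(self, a, b, expected):
        shared, pa, pb = de.signature_overlap(a, b)
        assert (set(shared), pa, pb) == expected

    def test_printed_cohort_sizes(self):
        """63- and 80-gene signatures sharing 27 genes: 43% and 34%."""
        a = [f"x{i}" for i in range(63)]
        b = a[:27] + [f"y{i}" for i in range(53)]
        shared, pa, pb = de.signature_overlap(a, b)
        assert (len(shared), pa, pb) == (27, 43, 34)


class TestOpenChromatin:
    def fixture(self, rng, delta=0.0, n_in=20, n_out=20):
        genes = [f"G{i}" for i in range(n_in + n_out)]
        models = pd.DataFrame(
            {
                "gene": genes, "chromosome": "chrX",
                "tss": np.arange(1, n_in + n_out + 1) * 100_000,
                "strand": "+", "region_tags": "",
            }
        )
        # peaks over the first n_in TSSs (BED half-open)
        peaks = pd.DataFrame(
            {
                "chromosome": "chrX",
                "start": models["tss"][:n_in] - 51,
                "end": models["tss"][:n_in] + 50,
            }
        )
        base = np.r_[np.full(n_in, 0.4 - delta), np.full(n_out, 0.4)]
        beta = pd.DataFrame(
            np.clip(base[:, None] + rng.normal(0, 0.05, (len(genes), 30)), 0, 1),
            index=genes, columns=[f"s{i}" for i in range(30)],
        )
        return beta, genes, models, peaks

    def test_window_zero_hits_only_covered_tss(self, rng):
        beta, genes, models, peaks = self.fixture(rng, n_in=1, n_out=3)
        flags, _, _ = de.open_chromatin_contrast(
            beta, genes, models, peaks, window_bp=0
        )
        assert flags["G0"] and not flags[["G1", "G2", "G3"]].any()

    def test_null_calibration(self, rng):
        """With identical beta distributions the Welch p-value is uniform."""
        ps = []
        for _ in range(200):
            beta, genes, models, peaks = self.fixture(rng, delta=0.0)
            _, _, p = de.open_chromatin_contrast(beta, genes, models, peaks)
            ps.append(p)
        ps = np.array(ps)
        assert 0.42 < ps.mean() < 0.58
        assert 0.005 <= (ps < 0.05).mean() <= 0.12

    def test_planted_difference_detected(self, rng):
        beta, genes, models, peaks = self.fixture(rng, delta=0.2)
        _, t, p = de.open_chromatin_contrast(beta, genes, models, peaks)
        assert t < 0 and p < 0.01

    def test_empty_side_rejected(self, rng):
        beta, genes, models, peaks = self.fixture(rng)
        with pytest.raises(ValueError):
            de.open_chromatin_contrast(
                beta, genes, models, peaks.iloc[:0], window_bp=0
            )
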