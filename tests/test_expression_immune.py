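import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from metpair.expression_immune import (
    cluster_samples,
    differential_methylation,
    immune_score,
    methylation_expression_filter,
    normalize_log_cpm,
    select_variable_genes,
    zscore_genes,
)


class TestNormalization:
    def test_hand_log_cpm(self):
        counts = pd.DataFrame({"s1": [10.0, 90.0], "s2": [50.0, 50.0]},
                              index=["g1", "g2"])
        out = normalize_log_cpm(counts)
        assert out.loc["g1", "s1"] == pytest.approx(
            np.log2(1e6 * 10 / 100 + 1))
        assert out.loc["g2", "s2"] == pytest.approx(
            np.log2(1e6 * 50 / 100 + 1))

    def test_identical_samples_identical_columns(self):
        counts = pd.DataFrame({"s1": [5.0, 7.0], "s2": [5.0, 7.0]},
                              index=["g1", "g2"])
        out = normalize_log_cpm(counts)
        assert (out["s1"] == out["s2"]).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_log_cpm(pd.DataFrame({"s": [-1.0]}, index=["g"]))

    def test_zscore_drops_constant_gene(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 4.0],
                          "s3": [1.0, 6.0]}, index=["flat", "var"])
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_genes(m)
        assert list(z.index) == ["var"]
        assert z.loc["var"].mean() == pytest.approx(0.0)
        assert z.loc["var"].std(ddof=1) == pytest.approx(1.0)


class TestImmuneScore:
    z = pd.DataFrame({"s1": [1.0, 3.0, -5.0], "s2": [0.0, 0.0, 2.0]},
                     index=["IMM1", "IMM2", "OTHER"])

    def test_mean_of_panel_genes(self):
        score = immune_score(self.z, ["IMM1", "IMM2"])
        assert score["s1"] == pytest.approx(2.0)
        assert score["s2"] == pytest.approx(0.0)

    def test_invariant_to_non_panel_genes(self):
        altered = self.z.copy()
        altered.loc["OTHER"] = 99.0
        a = immune_score(self.z, ["IMM1", "IMM2"])
        b = immune_score(altered, ["IMM1", "IMM2"])
        pd.testing.assert_series_equal(a, b)

    def test_linear_in_uniform_shift(self):
        shifted = self.z.copy()
        shifted.loc[["IMM1", "IMM2"]] += 1.5
        a = immune_score(self.z, ["IMM1", "IMM2"])
        b = immune_score(shifted, ["IMM1", "IMM2"])
        assert np.allclose(b - a, 1.5)

    def test_missing_genes_warn_and_all_missing_error(self):
        with pytest.warns(UserWarning, match="missing"):
            immune_score(self.z, ["IMM1", "ABSENT"])
        with pytest.raises(ValueError):
            immune_score(self.z, ["ABSENT"])

    def test_metastasis_scores_lower_in_simulation(self, mono_patient):
        bundle, truth = mono_patient
        z = zscore_genes(normalize_log_cpm(bundle.expression))
        from metpair.synthetic_cohort import immune_panel

        score = immune_score(z, immune_panel())
        assert score[bundle.metastasis_id] < score[bundle.primary_id]


class TestVariableGenes:
    def test_threshold_strict(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 10)
        m = pd.DataFrame(
            {f"s{i}": [0.0, base[i] * 3, base[i]] for i in range(10)},
            index=["flat", "wide", "narrow"])
        out = select_variable_genes(m, sd_threshold=2.0)
        assert "flat" not in out
        assert "wide" in out

    def test_hand_sd(self):
        vals = [1.0, 3.0, 6.0, 10.0]
        m = pd.DataFrame([vals], index=["g"],
                         columns=[f"s{i}" for i in range(4)])
        sd = np.std(vals, ddof=1)
        assert sd > 2.0
        assert select_variable_genes(m) == ["g"]

    def test_zero_threshold_keeps_all_non_constant(self):
        m = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 6.0]},
                         index=["flat", "var"])
        assert select_variable_genes(m, sd_threshold=0.0) == ["var"]


class TestClusterSamples:
    def test_duplicate_samples_merge_first(self):
        rng = np.random.default_rng(12)
        g = rng.normal(0, 1, 30)
        h = rng.normal(0, 1, 30)
        m = pd.DataFrame({"a": g, "b": g + rng.normal(0, 1, 30),
                          "dup1": h, "dup2": h.copy()})
        z, order = cluster_samples(m)
        first = z[0]
        merged = {order[int(first[0])], order[int(first[1])]}
        assert merged == {"dup1", "dup2"}

    def test_two_blocks_split_at_top(self):
        rng = np.random.default_rng(13)
        sig = rng.normal(0, 1, 40)
        cols = {}
        for i in range(3):
            cols[f"x{i}"] = sig + rng.normal(0, 0.1, 40)
        for i in range(3):
            cols[f"y{i}"] = -sig + rng.normal(0, 0.1, 40)
        z, order = cluster_samples(pd.DataFrame(cols))
        assign = hierarchy.fcluster(z, t=2, criterion="maxclust")
        groups = {}
        for lab, sample in zip(assign, order):
            groups.setdefault(lab, set()).add(sample[0])
        assert set(map(frozenset, groups.values())) == {
            frozenset({"x"}), frozenset({"y"})}

    def test_three_samples_two_merges(self):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(rng.normal(0, 1, (20, 3)),
                         columns=["a", "b", "c"])
        z, _ = cluster_samples(m)
        assert z.shape[0] == 2

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame({"a": [1.0], "b": [2.0]}))


class TestMethylationExpression:
    def test_perfect_anticorrelation_kept(self):
        e = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["g"],
                         columns=list("abcde"))
        b = pd.DataFrame([[0.9, 0.7, 0.5, 0.3, 0.1]], index=["g"],
                         columns=list("abcde"))
        assert methylation_expression_filter(b, e) == ["g"]

    def test_constant_row_excluded(self):
        e = pd.DataFrame([[1.0, 2, 3, 4]], index=["g"], columns=list("abcd"))
        b = pd.DataFrame([[0.5, 0.5, 0.5, 0.5]], index=["g"],
                         columns=list("abcd"))
        assert methylation_expression_filter(b, e) == []

    def test_null_exclusion_rate_matches_permutation(self):
        rng = np.random.default_rng(15)
        n_genes, n_samples = 300, 10
        e = pd.DataFrame(rng.normal(0, 1, (n_genes, n_samples)),
                         columns=[f"s{i}" for i in range(n_samples)])
        b = pd.DataFrame(rng.uniform(0, 1, (n_genes, n_samples)),
                         index=e.index, columns=e.columns)
        kept = methylation_expression_filter(b, e)
        # permutation oracle: null probability of rho <= -0.5 at n=10
        null = []
        x = np.arange(n_samples, dtype=float)
        for _ in range(3000):
            y = rng.permutation(n_samples).astype(float)
            from scipy import stats

            null.append(stats.spearmanr(x, y).statistic <= -0.5)
        p_null = np.mean(null)
        se = 3 * np.sqrt(p_null * (1 - p_null) / n_genes + 1e-6)
        assert abs(len(kept) / n_genes - p_null) <= max(se, 0.05)

    def test_simulated_regulated_genes_found(self, mono_patient):
        bundle, _ = mono_patient
        logcpm = normalize_log_cpm(bundle.expression)
        kept = methylation_expression_filter(bundle.methylation, logcpm)
        regulated = [g for g in bundle.methylation.index[:40]]
        # most of the constructed anti-correlated genes pass at n=3 samples
        assert len(set(kept) & set(regulated)) >= 30


class TestDifferentialMethylation:
    def _pairs(self, rng, n_genes=6, n_pairs=8, shift=0.0):
        cols = [f"pt{i}" for i in range(n_pairs)]
        p = pd.DataFrame(rng.uniform(0.3, 0.7, (n_genes, n_pairs)),
                         columns=cols)
        m = p + shift
        return p, m

    def test_identical_pairs_p_one(self):
        rng = np.random.default_rng(16)
        p, _ = self._pairs(rng)
        out = differential_methylation(p, p.copy())
        assert (out["p"] == 1.0).all()

    def test_hand_bh_adjustment(self):
        from statsmodels.stats.multitest import multipletests

        pvals = [0.01, 0.02, 0.03, 0.04]
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(q, 0.04)

    def test_shifted_genes_significant(self):
        rng = np.random.default_rng(17)
        p, m = self._pairs(rng, shift=0.3)
        out = differential_methylation(p, m)
        # n=8 pairs: min attainable two-sided p = 2/2^8
        assert np.allclose(out["p"].values, 2 / 256)

    def test_q_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(18)
        p = pd.DataFrame(rng.uniform(0.1, 0.9, (20, 6)),
                         columns=[f"pt{i}" for i in range(6)])
        m = pd.DataFrame(rng.uniform(0.1, 0.9, (20, 6)),
                         columns=[f"pt{i}" for i in range(6)])
        out = differential_methylation(p, m).sort_values("p")
        assert (out["q"] <= 1).all()
        assert (np.diff(out["q"].values) >= -1e-12).all()

    def test_too_few_pairs(self):
        rng = np.random.default_rng(19)
        p, m = self._pairs(rng, n_pairs=3)
        with pytest.raises(ValueError):
            differential_methylation(p, m)
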