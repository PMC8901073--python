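import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

import pigbiome as pb
from pigbiome.diversity import (alpha_indices, alpha_table, baseline_adjust,
                                bray_curtis, nmds, permanova)
from pigbiome.reference import load_alpha_summary_reference

from test_otu import make_table

# ---------------------------------------------------------------- oracles


def shannon_oracle(counts):
    p = counts / counts.sum()
    p = p[p > 0]
    return -(p * np.log2(p)).sum()


def chao1_oracle(counts):
    s = (counts > 0).sum()
    f1 = (counts == 1).sum()
    f2 = (counts == 2).sum()
    return s + f1 * (f1 - 1) / (2 * (f2 + 1))


def ace_oracle(counts, rare=10):
    c = counts[counts > 0]
    s_abund = (c > rare).sum()
    rare_c = c[c <= rare]
    n_rare = rare_c.sum()
    f1 = (rare_c == 1).sum()
    c_ace = 1 - f1 / n_rare
    ks = np.arange(1, rare + 1)
    fk = np.array([(rare_c == k).sum() for k in ks])
    g2 = max((rare_c.size / c_ace) * (ks * (ks - 1) * fk).sum()
             / (n_rare * (n_rare - 1)) - 1, 0)
    return s_abund + rare_c.size / c_ace + f1 / c_ace * g2


def fisher_oracle(counts):
    s, n = (counts > 0).sum(), counts.sum()
    lo, hi = 1e-10, 1e10
    for _ in range(200):
        mid = (lo + hi) / 2
        if mid * np.log(1 + n / mid) < s:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def pseudo_f_oracle(d, labels):
    """Naive double-loop PERMANOVA pseudo-F."""
    n = len(labels)
    ss_total = sum(d[i, j] ** 2 for i in range(n)
                   for j in range(i + 1, n)) / n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d[i, j] ** 2 for a, i in enumerate(idx)
                         for j in idx[a + 1:]) / len(idx)
    k = len(groups)
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def random_count_table(rng, n_taxa, n_samples):
    counts = rng.integers(0, 40, (n_taxa, n_samples))
    counts[:, counts.sum(axis=0) == 0] += 1
    counts[counts.sum(axis=1) == 0, 0] += 1
    return counts


# ------------------------------------------------------------------ alpha


class TestAlphaIndices:
    def test_uniform_four_taxa(self):
        table = make_table([[1], [1], [1], [1]])
        out = alpha_indices(table, indices=("observed_otus", "shannon",
                                            "simpson", "equitability",
                                            "simpson_e"))
        assert out.loc["s0", "shannon"] == pytest.approx(2.0)
        assert out.loc["s0", "equitability"] == pytest.approx(1.0)
        assert out.loc["s0", "simpson"] == pytest.approx(0.75)
        assert out.loc["s0", "simpson_e"] == pytest.approx(1.0)

    def test_chao1_worked_example(self):
        table = make_table([[1], [1], [2], [3]])
        out = alpha_indices(table)
        assert out.loc["s0", "chao1"] == pytest.approx(4.5)

    def test_chao1_equals_richness_without_singletons(self):
        table = make_table([[5], [3], [2]])
        out = alpha_indices(table)
        assert out.loc["s0", "chao1"] == out.loc["s0", "observed_otus"]

    def test_fisher_alpha_against_bisection(self):
        table = make_table([[50], [20], [10], [5], [5], [4], [3], [2], [1]])
        out = alpha_indices(table)
        counts = table.counts["s0"].to_numpy()
        assert out.loc["s0", "fisher_alpha"] == pytest.approx(
            fisher_oracle(counts), abs=1e-6)

    def test_richness_estimators_refuse_non_integer(self, sim_dataset):
        with pytest.raises(ValueError, match="integer raw counts"):
            alpha_indices(sim_dataset["norm"], indices=("chao1",))

    def test_invariant_bounds(self, sim_dataset):
        out = alpha_table(sim_dataset["filtered"], sim_dataset["norm"])
        assert ((out["simpson"] >= 0) & (out["simpson"] < 1)).all()
        assert ((out["equitability"] >= 0)
                & (out["equitability"] <= 1)).all()
        assert (out["chao1"] >= out["observed_otus"]).all()
        assert (out["ACE"] >= out["observed_otus"] - 1e-9).all()

    def test_merging_taxa_never_increases_shannon(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.integers(1, 30, rng.integers(3, 12))
            merged = np.concatenate(([counts[0] + counts[1]], counts[2:]))
            assert (shannon_oracle(merged)
                    <= shannon_oracle(counts) + 1e-12)

    def test_equitability_consistent_with_published_cells(self):
        ref = load_alpha_summary_reference()
        cells = ["pre_white", "pre_oil", "pre_traditional",
                 "post_white", "post_oil", "post_traditional",
                 "pre_overall", "post_overall"]
        for cell in cells:
            h = ref.loc["shannon", cell]
            s = ref.loc["observed_otus", cell]
            e = ref.loc["equitability", cell]
            assert abs(e - h / np.log2(s)) <= 0.02


class TestBaselineAdjust:
    def test_group_means_zero_at_baseline(self, sim_dataset):
        alpha = alpha_table(sim_dataset["filtered"], sim_dataset["norm"])
        meta = sim_dataset["filtered"].metadata
        adj = baseline_adjust(alpha, meta)
        at_t0 = adj.loc[meta["timepoint"] == "T0"]
        means = at_t0.groupby(meta["treatment"]).mean()
        assert np.allclose(means.to_numpy(), 0.0, atol=1e-10)

    def test_constant_series_adjusts_to_zero(self):
        meta = pd.DataFrame(
            {"pig": ["p1"] * 4, "treatment": ["white"] * 4,
             "timepoint": list(pb.TIMEPOINTS)},
            index=[f"s{i}" for i in range(4)])
        alpha = pd.DataFrame({"shannon": [3.0] * 4}, index=meta.index)
        adj = baseline_adjust(alpha, meta)
        assert np.allclose(adj["shannon"], 0.0)

    def test_between_timepoint_differences_unchanged(self, sim_dataset):
        alpha = alpha_table(sim_dataset["filtered"], sim_dataset["norm"])
        meta = sim_dataset["filtered"].metadata
        adj = baseline_adjust(alpha, meta)
        pig = meta["pig"].iloc[0]
        mine = meta.index[meta["pig"] == pig]
        raw_diff = alpha.loc[mine, "shannon"].diff().dropna()
        adj_diff = adj.loc[mine, "shannon"].diff().dropna()
        assert np.allclose(raw_diff, adj_diff)


# ------------------------------------------------------------------- beta


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        table = make_table([[3, 3], [7, 7]])
        dm = bray_curtis(table)
        assert dm[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        table = make_table([[5, 0], [0, 9]])
        dm = bray_curtis(table)
        assert dm[0, 1] == 1.0

    def test_hand_formula(self):
        table = make_table([[6, 2], [4, 8]])
        dm = bray_curtis(table)
        assert dm[0, 1] == pytest.approx(0.4)


class TestNmds:
    def test_planar_distances_recovered(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(10, 2))
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(10)])
        _, stress = nmds(dm, k=2, seed=0)
        assert stress < 1e-3

    def test_duplicates_coincide(self):
        table = make_table([[3, 3, 9], [7, 7, 1], [2, 2, 5], [1, 1, 6]])
        coords, _ = nmds(bray_curtis(table), k=2, seed=0)
        assert np.allclose(coords.loc["s0"], coords.loc["s1"], atol=1e-6)

    def test_deterministic_given_seed(self, sim_dataset):
        dm = bray_curtis(sim_dataset["norm"])
        c1, s1 = nmds(dm, seed=4)
        c2, s2 = nmds(dm, seed=4)
        pd.testing.assert_frame_equal(c1, c2)
        assert s1 == s2

    def test_k_too_large_errors(self):
        table = make_table([[3, 1, 2], [1, 5, 2]])
        with pytest.raises(ValueError, match="k="):
            nmds(bray_curtis(table), k=3)


class TestPermanova:
    def test_separated_clusters_minimal_p(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.01, (6, 5))
        b = rng.normal(10, 0.01, (6, 5))
        d = np.sqrt(((np.vstack([a, b])[:, None]
                      - np.vstack([a, b])[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(12)])
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, n_perm=999, seed=1)
        assert res["p_value"] == pytest.approx(1 / 1000)

    def test_pseudo_f_matches_double_loop_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(6, 13))
            vals = rng.random((n, 4))
            d = np.sqrt(((vals[:, None] - vals[None]) ** 2).sum(-1))
            dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
            labels = rng.choice(["a", "b", "c"], n).tolist()
            if len(set(labels)) < 2 or min(
                    labels.count(g) for g in set(labels)) < 1:
                continue
            res = permanova(dm, labels, n_perm=9, seed=0)
            assert res["pseudo_F"] == pytest.approx(
                pseudo_f_oracle(d, labels), abs=1e-10)

    def test_agrees_with_skbio(self, sim_dataset):
        dm = bray_curtis(sim_dataset["norm"])
        labels = sim_dataset["norm"].metadata["period"]
        ours = permanova(dm, labels, n_perm=999, seed=2)
        theirs = skbio_permanova(dm, labels.to_numpy(), permutations=999)
        assert ours["pseudo_F"] == pytest.approx(theirs["test statistic"])
        assert ours["p_value"] == pytest.approx(theirs["p-value"], abs=0.02)

    def test_strata_respects_grouping(self, sim_dataset):
        dm = bray_curtis(sim_dataset["norm"])
        meta = sim_dataset["norm"].metadata
        res = permanova(dm, meta["period"], n_perm=99, seed=3,
                        strata=meta["pig"])
        assert 0 < res["p_value"] <= 1

    def test_single_group_errors(self):
        table = make_table([[3, 1, 2], [1, 5, 2]])
        with pytest.raises(ValueError, match="two groups"):
            permanova(bray_curtis(table), ["a", "a", "a"])
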