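"""Rank tests, fold change, stratification and clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from plasmir import (
    CountMatrix,
    DetectionRule,
    cluster_heatmap,
    de_analyze,
    detection_flags,
    dunn_posthoc,
    fold_change,
    kruskal_wallis,
    stratify,
)

EXAMPLE = [[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]]


def exact_permutation_p(groups) -> float:
    """Exhaustive permutation p of the tie-corrected H statistic.

    Enumerates every assignment of the pooled observations to the group
    sizes (multiset combinations) and counts those with H >= observed.
    """
    import scipy.stats as st

    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    sizes = [len(g) for g in groups]
    ranks = st.rankdata(pooled)
    n = len(pooled)
    tie = 0.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = float((counts ** 3 - counts).sum())
    denom = 1.0 - tie / (n ** 3 - n)

    r = [float(x) for x in ranks]
    total_sum = sum(r)
    scale = 12.0 / (n * (n + 1))
    shift = 3.0 * (n + 1)

    def h_of_sums(sums):
        s = sum(sq * sq / k for sq, k in zip(sums, sizes))
        h = scale * s - shift
        return h / denom if denom > 0 else 0.0

    bounds = np.concatenate([[0], np.cumsum(sizes)])
    h_obs = h_of_sums(
        [sum(r[bounds[i]: bounds[i + 1]]) for i in range(len(sizes))]
    )

    idx = tuple(range(n))
    hits = total = 0
    thresh = h_obs - 1e-12
    for c1 in itertools.combinations(idx, sizes[0]):
        s1 = sum(r[i] for i in c1)
        rest1 = tuple(i for i in idx if i not in set(c1))
        for c2 in itertools.combinations(rest1, sizes[1]):
            s2 = sum(r[i] for i in c2)
            rest2 = tuple(i for i in rest1 if i not in set(c2))
            for c3 in itertools.combinations(rest2, sizes[2]):
                s3 = sum(r[i] for i in c3)
                s4 = total_sum - s1 - s2 - s3
                total += 1
                if h_of_sums((s1, s2, s3, s4)) >= thresh:
                    hits += 1
    return hits / total


class TestKruskalWallis:
    def test_printed_example(self):
        h, p = kruskal_wallis(EXAMPLE)
        assert h == pytest.approx(10.3846, abs=1e-4)
        assert p == pytest.approx(0.0156, abs=2e-4)

    def test_all_tied(self):
        h, p = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert (h, p) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda x: 3 * x + 1, np.arctan, lambda x: x ** 3]
    )
    def test_monotone_invariance(self, transform):
        rng = np.random.default_rng(8)
        groups = [rng.normal(size=5) for _ in range(3)]
        h0, _ = kruskal_wallis(groups)
        h1, _ = kruskal_wallis([transform(np.asarray(g)) for g in groups])
        assert h1 == pytest.approx(h0, abs=1e-10)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="observation"):
            kruskal_wallis([[1, 2], []])

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # the 4x3 example is the perfectly separated configuration, so its
        # exact permutation p is tiny; the Monte Carlo estimate must agree
        exact = exact_permutation_p(EXAMPLE)
        assert exact == pytest.approx(24 / 369600)
        h, p_mc = kruskal_wallis(EXAMPLE, method="permutation", n_permutations=100_000, seed=1)
        assert h == pytest.approx(10.3846, abs=1e-4)
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(p_mc - exact) < 4 * se + 2e-5

    def test_permutation_matches_chi2_at_moderate_n(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, size=12) for m in (0.0, 0.3, 0.6, 0.2)]
        _, p_chi2 = kruskal_wallis(groups)
        _, p_mc = kruskal_wallis(groups, method="permutation", n_permutations=100_000, seed=2)
        assert p_mc == pytest.approx(p_chi2, abs=0.01)


class TestDunn:
    def test_printed_example_pair(self):
        res = dunn_posthoc(EXAMPLE)
        z14 = res.loc[(res.cohort_a == "cohort1") & (res.cohort_b == "cohort4"), "z"].iloc[0]
        assert abs(z14) == pytest.approx(3.0571, abs=1e-4)
        assert z14 == pytest.approx(-(11 - 2) / math.sqrt(13 * 2 / 3), abs=1e-4)

    def test_identical_cohorts(self):
        res = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert res["z"].iloc[0] == pytest.approx(0.0)
        assert res["p_adj"].iloc[0] == 1.0

    def test_antisymmetry(self):
        a = dunn_posthoc(EXAMPLE)
        b = dunn_posthoc(EXAMPLE[::-1])
        # reversing group order flips the sign of each pairwise z
        z_ab = a.set_index(["cohort_a", "cohort_b"])["z"]
        z_ba = b.set_index(["cohort_a", "cohort_b"])["z"]
        assert z_ab[("cohort1", "cohort4")] == pytest.approx(-z_ba[("cohort1", "cohort4")])

    @given(hst.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_adjustment_bounds(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 20, size=rng.integers(2, 7)) for _ in range(4)]
        res = dunn_posthoc(groups)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert (res["p_adj"] <= 1.0).all()
        holm = dunn_posthoc(groups, adjust="holm")
        assert (holm["p_adj"] <= res["p_adj"] + 1e-12).all()


class TestFoldChange:
    @pytest.mark.parametrize(
        "stage,control,expected", [(30, 10, 2.0), (10, 10, 0.0), (5, 10, -0.5)]
    )
    def test_formula(self, stage, control, expected):
        assert fold_change(stage, control) == pytest.approx(expected)

    def test_control_absent_sentinel(self):
        assert math.isnan(fold_change(10.0, 0.0))


class TestStratify:
    COHORTS = ["Control", "FIGO_I", "FIGO_III", "FIGO_IV"]

    def make(self, flags, p):
        det = pd.DataFrame([dict(zip(self.COHORTS, flags))], index=["x"])
        return stratify(det, pd.Series({"x": p}))["x"]

    def test_detected_everywhere_significant(self):
        assert self.make([True, True, True, True], 0.01) == "group1"

    def test_detected_everywhere_not_significant(self):
        assert self.make([True, True, True, True], 0.2) == "none"

    def test_patient_early_stage_only(self):
        assert self.make([False, True, False, False], 0.5) == "group2"

    def test_patient_all_stages(self):
        assert self.make([False, True, True, True], 0.5) == "group3"

    def test_middle_stage_only_falls_through(self):
        assert self.make([False, False, True, False], 0.01) == "none"

    @given(hst.lists(hst.booleans(), min_size=4, max_size=4), hst.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_total_and_exclusive(self, flags, p):
        out = self.make(flags, p)
        assert out in {"group1", "group2", "group3", "none"}

    def test_detection_rule(self):
        counts = pd.DataFrame(
            {"a1": [5.0, 0.0], "a2": [0.0, 0.0], "b1": [1.0, 2.0], "b2": [3.0, 0.0]},
            index=["p1", "p2"],
        )
        cm = CountMatrix(
            counts=counts,
            probe_class=pd.Series(["endogenous", "endogenous"], index=["p1", "p2"]),
            cohorts=pd.Series(["A", "A", "B", "B"], index=counts.columns),
        )
        det = detection_flags(cm, DetectionRule(min_fraction=0.5, threshold=0.0))
        assert det.loc["p1"].tolist() == [True, True]
        # p2 in cohort B: >0 in exactly half the samples, at the boundary
        assert det.loc["p2"].tolist() == [False, True]


class TestDeAnalyze:
    def test_planted_probe_becomes_group1(self, seeded_run):
        cfg, cm, truth = seeded_run
        from plasmir import normalize

        norm, _ = normalize(cm)
        de = de_analyze(norm)
        g1 = [p for p, _ in cfg.planted_group1]
        assert (de.loc[g1, "group"] == "group1").mean() >= 0.75
        # planted upregulation: positive fold change in every stage
        assert (de.loc[g1, ["fc_FIGO_I", "fc_FIGO_III", "fc_FIGO_IV"]] > 0).all().all()

    def test_groups_mutually_exclusive_by_construction(self, seeded_run):
        _, cm, _ = seeded_run
        from plasmir import normalize

        norm, _ = normalize(cm)
        de = de_analyze(norm)
        assert de["group"].isin(["group1", "group2", "group3", "none"]).all()


class TestClusterHeatmap:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame(
            {"s1": [1.0, 1.0, 9.0], "s2": [4.0, 4.0, 2.0]},
            index=["a", "b", "c"],
        )
        res = cluster_heatmap(df)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_first_merge_is_closest_pair_unscaled(self):
        df = pd.DataFrame(
            {"s1": [0.0, 0.0, 0.0], "s2": [0.0, 3.0, 10.0]},
            index=["r1", "r2", "r3"],
        )
        res = cluster_heatmap(df, log_transform=False, scale=False)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}
        assert res.linkage[0, 2] == pytest.approx(3.0)

    def test_row_permutation_leaves_topology_unchanged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.poisson(50, size=(6, 8)).astype(float),
            index=[f"m{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(8)],
        )
        shuffled = df.sample(frac=1.0, random_state=1)
        a = cluster_heatmap(df)
        b = cluster_heatmap(shuffled)
        assert a.newick == b.newick
        pd.testing.assert_frame_equal(a.ordered, b.ordered)

    def test_constant_row_flagged(self):
        df = pd.DataFrame(
            {"s1": [2.0, 1.0], "s2": [2.0, 5.0]},
            index=["const", "var"],
        )
        res = cluster_heatmap(df)
        assert res.constant_rows == ["const"]
        assert (res.ordered.loc["const"] == 0).all()

    def test_newick_is_parseable(self):
        import io

        import skbio

        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            rng.poisson(30, size=(5, 6)).astype(float),
            index=[f"m{i}" for i in range(5)],
        )
        res = cluster_heatmap(df)
        tree = skbio.TreeNode.read(io.StringIO(res.newick))
        assert {t.name for t in tree.tips()} == set(df.index)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            cluster_heatmap(pd.DataFrame({"s": [1.0]}, index=["only"]))
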