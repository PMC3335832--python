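"""Three-criterion DE caller: gate, Welch test, BH step-up, fold change."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from edsig import diffexpr
from conftest import tiny_matrix


class TestDetectionGate:
    @pytest.mark.parametrize(
        "detected_higher, expected",
        [(0.8, True), (0.7, False), (1.0, True), (0.0, False)],
    )
    def test_boundary_on_higher_group(self, detected_higher, expected):
        gated = diffexpr.detection_gate(
            np.array([5.0]), np.array([3.0]), np.array([detected_higher]), np.array([0.0])
        )
        assert gated[0] == expected

    def test_only_higher_group_counts(self):
        # lower-mean group fully undetected, higher fully detected -> gated in
        gated = diffexpr.detection_gate(np.array([3.0]), np.array([5.0]), np.array([0.0]), np.array([1.0]))
        assert gated[0]

    def test_tie_in_means_is_symmetric(self):
        gated = diffexpr.detection_gate(np.array([4.0]), np.array([4.0]), np.array([0.0]), np.array([0.9]))
        assert gated[0]

    def test_lowering_detect_p_never_gates_in(self, default_prep):
        """Gate monotonicity on real generator output: a stricter detection
        threshold can only shrink the tested set."""
        prep, _, _ = default_prep
        a = prep.samples_in_group("IPAH")
        b = prep.samples_in_group("Control")
        sub = prep.subset_probes(list(prep.probes[:500]))
        mean_a = sub.values[a].mean(axis=1).to_numpy()
        mean_b = sub.values[b].mean(axis=1).to_numpy()
        gates = []
        for detect_p in (0.01, 0.004, 0.001):
            fa = (sub.detection_p[a].to_numpy() < detect_p).mean(axis=1)
            fb = (sub.detection_p[b].to_numpy() < detect_p).mean(axis=1)
            gates.append(diffexpr.detection_gate(mean_a, mean_b, fa, fb))
        assert not (~gates[0] & gates[1]).any()
        assert not (~gates[1] & gates[2]).any()


class TestWelch:
    def test_identical_groups(self):
        t, df, p = diffexpr.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0 and p == pytest.approx(1.0)

    def test_matches_independent_oracle(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        t, df, p = diffexpr.welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert df == pytest.approx(ref.df, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 5.0], [0.5, 4.0, 4.5, 9.0]
        t1, _, p1 = diffexpr.welch_t(a, b)
        t2, _, p2 = diffexpr.welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_conventions(self):
        t, _, p = diffexpr.welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.raises(ValueError, match="zero variance"):
            diffexpr.welch_t([2.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValueError, match="at least 2"):
            diffexpr.welch_t([2.0], [1.0, 2.0])


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(diffexpr.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(diffexpr.bh_fdr([0.2, 0.2, 0.2, 0.2]), 0.2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_in_p_and_bounded(self, p):
        q = diffexpr.bh_fdr(p)
        assert (q <= 1).all() and (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(diffexpr.bh_fdr(p), q_ref, atol=1e-12)


class TestFoldChange:
    def test_known_ratios(self):
        assert diffexpr.geometric_fold_change(9.0, 8.0) == pytest.approx(2.0)
        assert diffexpr.geometric_fold_change(8.0, 8.0) == pytest.approx(1.0)
        assert diffexpr.geometric_fold_change(8.585, 8.0) == pytest.approx(1.5, abs=1e-3)


class TestCallDe:
    def _matrix(self):
        rng = np.random.default_rng(1)
        groups = ["A"] * 10 + ["B"] * 10
        vals = {}
        # p0: strong shift passing all criteria; p1: shift too small for FC;
        # p2: pure noise; p3: gated out (never detected)
        vals["p0"] = list(np.r_[rng.normal(10, 0.1, 10), rng.normal(8, 0.1, 10)])
        vals["p1"] = list(np.r_[rng.normal(8.3, 0.1, 10), rng.normal(8.0, 0.1, 10)])
        vals["p2"] = list(rng.normal(8, 0.1, 20))
        vals["p3"] = list(rng.normal(5, 0.1, 20))
        det = {p: [0.001] * 20 for p in ("p0", "p1", "p2")}
        det["p3"] = [0.9] * 20
        return tiny_matrix(vals, groups=groups, detection=det)

    def test_criteria_flags(self):
        de = diffexpr.call_de(self._matrix(), "A", "B")
        assert bool(de.loc["p0", "significant"])
        assert bool(de.loc["p1", "tested"]) and not de.loc["p1", "significant"]  # FC fails
        assert not de.loc["p2", "significant"]
        assert not de.loc["p3", "tested"] and np.isnan(de.loc["p3", "p"])
        assert de.loc["p0", "direction"] == "up"
        assert de.loc["p0", "fold_change"] == pytest.approx(4.0, rel=0.2)

    def test_fdr_universe_is_gated_probes_only(self):
        de = diffexpr.call_de(self._matrix(), "A", "B")
        tested = de[de["tested"]]
        np.testing.assert_allclose(
            tested["q"].to_numpy(), diffexpr.bh_fdr(tested["p"].to_numpy()), atol=1e-15
        )

    def test_small_group_rejected(self):
        m = self._matrix().subset_samples([f"s{i}" for i in [0, 10, 11, 12]])
        with pytest.raises(ValueError, match=">= 2 samples"):
            diffexpr.call_de(m, "A", "B")

    def test_permuted_labels_keep_error_control(self, default_prep):
        """Shuffling group labels of a planted cohort must not produce
        significant calls beyond nominal error control."""
        prep, _, _ = default_prep
        rng = np.random.default_rng(42)
        shuffled = prep.sample_annotations.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        from dataclasses import replace

        perm = replace(prep, sample_annotations=shuffled)
        de = diffexpr.call_de(perm, "IPAH", "Control")
        assert int(de["significant"].sum()) <= 5


class TestVennPartition:
    def test_two_lists(self):
        regions = diffexpr.venn_partition({"c1": ["a", "b"], "c2": ["b", "c"]})
        assert regions[("c1",)] == ["a"]
        assert regions[("c2",)] == ["c"]
        assert regions[("c1", "c2")] == ["b"]

    def test_identical_lists_land_in_full_intersection(self):
        lists = {k: ["x", "y"] for k in ("a", "b", "c")}
        regions = diffexpr.venn_partition(lists)
        assert regions[("a", "b", "c")] == ["x", "y"]
        assert all(v == [] for k, v in regions.items() if len(k) < 3)

    def test_region_sizes_sum_to_union(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(60)]
        lists = {f"c{j}": list(rng.choice(genes, 25, replace=False)) for j in range(3)}
        regions = diffexpr.venn_partition(lists)
        union = set().union(*lists.values())
        assert sum(len(v) for v in regions.values()) == len(union)

    def test_planted_shared_module_lands_in_intersection(self, default_prep):
        """Genes planted as up-regulated in every disease group appear in the
        triple intersection of the disease-vs-control up-lists."""
        prep, _, truth = default_prep
        up_lists = {}
        for g in ("SSc", "IPAH", "SSc-PAH"):
            de = diffexpr.call_de(prep, g, "Control")
            up_lists[g] = diffexpr.significant_genes(de, "up")
        regions = diffexpr.venn_partition(up_lists)
        shared_planted = set(truth.planted_de_genes["SSc_vs_Control"]["up"]) & set(
            truth.planted_de_genes["IPAH_vs_Control"]["up"]
        ) & set(truth.planted_de_genes["SSc-PAH_vs_Control"]["up"])
        core = set(regions[("SSc", "IPAH", "SSc-PAH")])
        assert shared_planted, "fixture should plant a shared module"
        # per-gene power compounds across the three contrasts (the smallest
        # group has 19 samples), so a majority — not all — of the shared
        # planted genes reach the triple intersection, and the intersection
        # itself is dominated by planted genes
        overlap = len(shared_planted & core) / len(shared_planted)
        assert overlap >= 0.6
        purity = len(core & shared_planted) / len(core)
        assert purity >= 0.9
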