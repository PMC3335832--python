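"""Parametric gene-set enrichment: metrics, scoring, landscape variant."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edsig import gse, preprocess


def _metric(values: dict[str, float], kind="zratio") -> gse.MetricVector:
    return gse.MetricVector(scores=pd.Series(values), kind=kind)


def _oracle_page(scores: dict[str, float], members: list[str]) -> tuple[float, float]:
    """Independent plain-Python evaluation of the size-adjusted z."""
    import math

    vals = list(scores.values())
    mu = sum(vals) / len(vals)
    delta = math.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals))
    hit = [scores[g] for g in members if g in scores]
    sm = sum(hit) / len(hit)
    z = (sm - mu) * math.sqrt(len(hit)) / delta
    return z, 2.0 * stats.norm.sf(abs(z))


class TestMetrics:
    def _gene_z(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(0, 1, (50, 12)),
                             index=[f"g{i}" for i in range(50)],
                             columns=[f"s{i}" for i in range(12)])
        return frame

    def test_zratio_standardized_over_genes(self):
        gz = self._gene_z()
        a, b = [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        metric = gse.zratio_metric(gz, a, b)
        assert metric.mu == pytest.approx(0.0, abs=1e-12)
        assert metric.delta == pytest.approx(1.0, abs=1e-12)

    def test_zratio_same_samples_degenerate(self):
        gz = self._gene_z()
        a = [f"s{i}" for i in range(6)]
        with pytest.warns(UserWarning, match="degenerate"):
            metric = gse.zratio_metric(gz, a, a)
        assert (metric.scores == 0).all()

    def test_difference_metric_shift_and_translation_invariance(self):
        gz = self._gene_z()
        a, b = [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        m1 = gse.difference_metric(gz, a, b)
        shifted = gse.difference_metric(gz + 7.5, a, b)
        np.testing.assert_allclose(m1.scores, shifted.scores, atol=1e-9)
        bumped = gz.copy()
        bumped.loc["g0", a] += 1.0
        m2 = gse.difference_metric(bumped, a, b)
        assert m2.scores["g0"] == pytest.approx(m1.scores["g0"] + 1.0)

    def test_zratio_antisymmetric_under_group_swap(self):
        gz = self._gene_z()
        a, b = [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)]
        f = gse.zratio_metric(gz, a, b).scores
        r = gse.zratio_metric(gz, b, a).scores
        np.testing.assert_allclose(f, -r, atol=1e-12)


class TestPageScore:
    def test_whole_universe_scores_zero(self):
        metric = _metric({f"g{i}": float(i) for i in range(30)})
        es = gse.page_score(metric, [f"g{i}" for i in range(30)], min_size=10)
        assert es.z == pytest.approx(0.0, abs=1e-12)
        assert es.p == pytest.approx(1.0)

    def test_top_decile_matches_oracle(self):
        scores = {f"g{i}": float(i + 1) for i in range(100)}
        metric = _metric(scores)
        members = [f"g{i}" for i in range(90, 100)]
        es = gse.page_score(metric, members, min_size=10)
        z_ref, p_ref = _oracle_page(scores, members)
        assert es.z == pytest.approx(z_ref, abs=1e-12)
        assert es.p == pytest.approx(p_ref, abs=1e-12)
        assert es.m == 10

    def test_small_set_unreported(self):
        metric = _metric({f"g{i}": float(i) for i in range(30)})
        es = gse.page_score(metric, ["g1", "g2"], min_size=10)
        assert not es.reported and np.isnan(es.z)

    def test_case_insensitive_symbol_match(self):
        metric = _metric({f"G{i}": float(i) for i in range(20)})
        es = gse.page_score(metric, [f"g{i}" for i in range(10)], min_size=10)
        assert es.m == 10

    def test_zero_delta_rejected(self):
        metric = _metric({f"g{i}": 1.0 for i in range(20)})
        with pytest.raises(ValueError, match="SD is zero"):
            gse.page_score(metric, [f"g{i}" for i in range(12)])

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(1)
        gz = pd.DataFrame(rng.normal(0, 1, (80, 10)), index=[f"g{i}" for i in range(80)],
                          columns=[f"s{i}" for i in range(10)])
        a, b = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        members = [f"g{i}" for i in range(15)]
        for builder in (gse.zratio_metric, gse.difference_metric):
            zf = gse.page_score(builder(gz, a, b), members).z
            zr = gse.page_score(builder(gz, b, a), members).z
            assert zf == pytest.approx(-zr, abs=1e-9)


class TestScoreCollection:
    def test_empty_collection_and_order_invariance(self):
        metric = _metric({f"g{i}": float(i) for i in range(40)})
        empty = gse.score_collection(metric, gse.GeneSetCollection())
        assert len(empty) == 0
        c1 = gse.GeneSetCollection()
        c1.add(gse.GeneSet("A", "", tuple(f"g{i}" for i in range(12))))
        c1.add(gse.GeneSet("B", "", tuple(f"g{i}" for i in range(20, 34))))
        c2 = gse.GeneSetCollection()
        c2.add(gse.GeneSet("B", "", tuple(f"g{i}" for i in range(20, 34))))
        c2.add(gse.GeneSet("A", "", tuple(f"g{i}" for i in range(12))))
        t1 = gse.score_collection(metric, c1)
        t2 = gse.score_collection(metric, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_down_module_negative_in_every_contrast(self, default_prep):
        """A module planted as down-regulated in all disease groups must score
        negative against controls in every contrast (the all-negative
        adaptive-immunity pattern)."""
        prep, _, truth = default_prep
        sample_z = preprocess.zscore_within_sample(prep)
        gene_z = gse.collapse_to_genes(sample_z, prep.probe_annotations)
        down_genes = tuple(
            prep.probe_annotations.reindex(truth.probes_in_module("IR_DR")).dropna().astype(str)
        )
        coll = gse.GeneSetCollection()
        coll.add(gse.GeneSet("IR_DR", "planted down-module", down_genes))
        ctrl = prep.samples_in_group("Control")
        for g in ("SSc", "IPAH", "SSc-PAH", "SSc-PH-ILD"):
            metric = gse.zratio_metric(gene_z, prep.samples_in_group(g), ctrl)
            table = gse.score_collection(metric, coll)
            assert table.loc[0, "z"] < -3


class TestSampleLandscape:
    def test_column_matches_manual_scoring(self):
        rng = np.random.default_rng(3)
        gz = pd.DataFrame(rng.normal(0, 1, (60, 4)), index=[f"g{i}" for i in range(60)],
                          columns=list("abcd"))
        coll = gse.GeneSetCollection()
        coll.add(gse.GeneSet("S", "", tuple(f"g{i}" for i in range(15))))
        scores, _ = gse.sample_landscape(gz, coll)
        for s in "abcd":
            metric = gse.MetricVector(scores=gz[s], kind="per_sample_z", label=s)
            manual = gse.page_score(metric, [f"g{i}" for i in range(15)])
            assert scores.loc["S", s] == pytest.approx(manual.z, abs=1e-12)

    def test_group_averaging(self):
        gz = pd.DataFrame(np.arange(40, dtype=float).reshape(10, 4),
                          index=[f"g{i}" for i in range(10)], columns=list("abcd"))
        gz = (gz - gz.mean()) / gz.std(ddof=0)
        coll = gse.GeneSetCollection()
        coll.add(gse.GeneSet("S", "", tuple(f"g{i}" for i in range(5))))
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        scores, view = gse.sample_landscape(gz, coll, groups=groups, min_size=5)
        assert view.loc["S", "x"] == pytest.approx(scores.loc["S", ["a", "b"]].mean())


class TestSignatureInDataset:
    def test_planted_signature_ranks_top(self, default_prep):
        prep, _, truth = default_prep
        sig_genes = tuple(
            prep.probe_annotations.reindex(truth.probes_in_module("EDS")).dropna().astype(str)
        )
        signature_set = gse.GeneSet("EDS_SIG", "planted signature", sig_genes)
        universe = list(gse.collapse_to_genes(prep.values, prep.probe_annotations).index)
        rng = np.random.default_rng(0)
        background = gse.GeneSetCollection(source="random")
        for i in range(120):
            size = int(rng.integers(15, 80))
            background.add(gse.GeneSet(f"BG{i}", "", tuple(rng.choice(universe, size, replace=False))))
        table = gse.score_signature_in_dataset(
            prep, {"IPAH_vs_Control": ("IPAH", "Control")}, signature_set, background
        )
        row = table.loc["IPAH_vs_Control"]
        assert row["reported"]
        assert row["z"] > 5
        assert row["rank"] <= max(1, int(0.01 * row["n_sets"]))

    def test_absent_signature_unreported(self, default_prep):
        prep, _, _ = default_prep
        ghost = gse.GeneSet("GHOST", "", ("NOSUCHGENE1", "NOSUCHGENE2"))
        background = gse.GeneSetCollection()
        universe = list(gse.collapse_to_genes(prep.values, prep.probe_annotations).index)
        background.add(gse.GeneSet("BG", "", tuple(universe[:30])))
        table = gse.score_signature_in_dataset(
            prep, {"c": ("IPAH", "Control")}, ghost, background
        )
        assert not table.loc["c", "reported"]
        assert np.isnan(table.loc["c", "z"])


class TestCollapseToGenes:
    def test_max_mean_probe_wins(self):
        values = pd.DataFrame(
            {"s0": [1.0, 5.0, 2.0], "s1": [1.0, 5.0, 2.0]},
            index=["pA_low", "pA_high", "pB"],
        )
        ann = pd.Series({"pA_low": "geneA", "pA_high": "GENEA", "pB": "geneB"})
        out = gse.collapse_to_genes(values, ann)
        assert list(out.index) == ["GENEA", "GENEB"]
        assert out.loc["GENEA", "s0"] == 5.0
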