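"""Nearest-neighbour clustering, HAS proximity, H4K16ac comparisons."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import embryocomp as ec
from embryocomp.spatial import _distance_to_intervals
from embryocomp.types import ValidationError


def nn_bruteforce(positions):
    pos = np.asarray(positions, float)
    out = []
    for i, p in enumerate(pos):
        others = np.delete(pos, i)
        out.append(np.abs(others - p).min())
    return float(np.mean(out))


def _ann_from_positions(positions, chrom="XL"):
    n = len(positions)
    frame = pd.DataFrame({
        "chromosome": chrom, "start": positions,
        "end": np.asarray(positions) + 100, "strand": "+",
        "neoY_orf": "not_applicable", "n_informative_snps": 1,
    }, index=[f"g{i}" for i in range(n)])
    return ec.GeneAnnotation(frame)


class TestNNDistance:
    def test_three_point_example(self):
        assert ec.nn_distance_stat([0, 10, 25]) == pytest.approx(35 / 3)

    def test_two_points_mean_is_separation(self):
        assert ec.nn_distance_stat([100, 240]) == 140

    def test_single_point_undefined(self):
        with pytest.raises(ValidationError):
            ec.nn_distance_stat([5])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 10**7), min_size=2, max_size=50, unique=True))
    def test_matches_all_pairs_bruteforce(self, positions):
        assert ec.nn_distance_stat(positions) == pytest.approx(
            nn_bruteforce(positions), rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(positions=st.lists(st.integers(0, 10**6), min_size=2, max_size=30,
                              unique=True),
           offset=st.integers(-10**5, 10**5), scale=st.integers(1, 50))
    def test_translation_invariant_and_scale_linear(self, positions, offset, scale):
        base = ec.nn_distance_stat(positions)
        shifted = ec.nn_distance_stat([p + offset for p in positions])
        scaled = ec.nn_distance_stat([p * scale for p in positions])
        assert shifted == pytest.approx(base, rel=1e-12)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestClusteringTest:
    def _labels(self, ann, compensated_genes, stage=5):
        labels = pd.Series("excluded", index=ann.gene_ids)
        labels[list(compensated_genes)] = "compensated"
        return ec.CompensationLabels(labels=labels, stage=stage)

    def _zyg_calls(self, ann, genes, stage=5):
        frame = pd.DataFrame({stage: ann.gene_ids.isin(genes)},
                             index=ann.gene_ids).astype("boolean")
        return ec.ZygoticCalls("allele_specific", frame)

    def test_contiguous_block_maximally_clustered(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(10**7, 60, replace=False))
        ann = _ann_from_positions(pos)
        block = [f"g{i}" for i in range(20, 30)]  # adjacent genes
        calls = self._zyg_calls(ann, set(ann.gene_ids))
        out = ec.clustering_test(self._labels(ann, block), ann, calls,
                                 n_reps=199, seed=0)
        assert out.iloc[0]["p"] == pytest.approx(1 / 200)

    def test_p_has_add_one_support(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(10**7, 40, replace=False))
        ann = _ann_from_positions(pos)
        calls = self._zyg_calls(ann, set(ann.gene_ids))
        genes = rng.choice(ann.gene_ids, 10, replace=False)
        out = ec.clustering_test(self._labels(ann, genes), ann, calls,
                                 n_reps=99, seed=3)
        p = out.iloc[0]["p"]
        assert p in {round((1 + k) / 100, 10) for k in range(100)}
        assert p >= 1 / 100

    def test_random_labels_uniform_p(self):
        """Labels drawn at random from the zygotic universe give uniform p."""
        from scipy import stats
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(10**7, 80, replace=False))
        ann = _ann_from_positions(pos)
        calls = self._zyg_calls(ann, set(ann.gene_ids))
        ps = []
        for i in range(120):
            genes = rng.choice(ann.gene_ids, 15, replace=False)
            out = ec.clustering_test(self._labels(ann, genes), ann, calls,
                                     n_reps=199, seed=1000 + i)
            ps.append(out.iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zygotic_null_absorbs_zygotic_clustering(self):
        """Clustered zygotic genes look significant against all genes but not
        against the zygotic universe."""
        cfg = ec.config_with(ec.default_config("pse_like", seed=59),
                             n_genes_per_chromosome={"2": 400, "4": 100},
                             zygotic_clustering=True)
        _, _, _, ann, truth = ec.simulate_experiment(cfg)
        zyg = truth.genes.index[truth.genes["is_zygotic"]]
        chrom2 = ann.genes_on("2")
        rng = np.random.default_rng(0)
        subset = rng.choice(list(zyg.intersection(chrom2)), 40, replace=False)
        labels = self._labels(ann, subset)
        calls = self._zyg_calls(ann, set(zyg))
        vs_all = ec.clustering_test(labels, ann, calls, null_universe="all",
                                    n_reps=499, seed=1)
        vs_zyg = ec.clustering_test(labels, ann, calls, null_universe="zygotic",
                                    n_reps=499, seed=1)
        p_all = vs_all[vs_all["chromosome"] == "2"].iloc[0]["p"]
        p_zyg = vs_zyg[vs_zyg["chromosome"] == "2"].iloc[0]["p"]
        assert p_all < 0.01
        assert p_zyg > 0.05

    def test_label_set_exceeding_universe_rejected(self):
        ann = _ann_from_positions([0, 100, 200, 300])
        labels = self._labels(ann, ["g0", "g1", "g2"])
        calls = self._zyg_calls(ann, {"g0", "g1"})
        with pytest.raises(ValidationError, match="larger than"):
            ec.clustering_test(labels, ann, calls, n_reps=9, seed=0)


class TestHasProximity:
    def _bias(self, ratios, stage=5):
        frame = pd.DataFrame({
            "female_mean": 10.0, "male_mean": 10.0 / np.asarray(ratios),
            "ratio": ratios, "included": True},
            index=[f"g{i}" for i in range(len(ratios))])
        return ec.BiasTable(frame, stage=stage)

    def test_lower_quartile_size_with_eight_genes(self):
        pos = [0, 1000, 3000, 6000, 50000, 60000, 70000, 80000]
        ann = _ann_from_positions(pos)
        has = pd.DataFrame({"chromosome": ["XL"], "start": [0], "end": [1100]})
        bias = self._bias([1.0] * 8)
        out = ec.has_proximity_test(bias, has, ann).iloc[0]
        assert out["n_near"] == 2
        assert out["n_far"] == 6

    def test_gene_inside_interval_distance_zero(self):
        pts = np.array([150.0])
        iv = pd.DataFrame({"chromosome": ["XL"], "start": [100], "end": [200]})
        assert _distance_to_intervals(pts, iv)[0] == 0.0

    def test_independent_ratios_uniform_p(self):
        from scipy import stats
        rng = np.random.default_rng(6)
        ps = []
        for i in range(80):
            pos = np.sort(rng.choice(10**6, 40, replace=False))
            ann = _ann_from_positions(pos)
            has = pd.DataFrame({"chromosome": ["XL"] * 3,
                                "start": rng.choice(10**6, 3),
                                "end": rng.choice(10**6, 3) + 500})
            bias = self._bias(rng.lognormal(0.5, 0.3, 40))
            out = ec.has_proximity_test(bias, has, ann)
            ps.append(out.iloc[0]["wilcoxon_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestH4K16acCompare:
    def _labels_from_sets(self, ann, compensated, uncompensated, stage=5):
        labels = pd.Series("excluded", index=ann.gene_ids)
        labels[list(compensated)] = "compensated"
        labels[list(uncompensated)] = "uncompensated"
        return ec.CompensationLabels(labels=labels, stage=stage)

    def test_identical_enrichment_unflagged(self):
        ann = _ann_from_positions(np.arange(40) * 1000)
        labels = self._labels_from_sets(ann, ann.gene_ids[:20], ann.gene_ids[20:])
        enrich = pd.Series(0.5, index=ann.gene_ids)
        out = ec.h4k16ac_compare(labels, enrich, ann, n_boot=200, seed=1)
        assert not out["compensated_above"].any()
        assert not out["compensated_below"].any()

    def test_enriched_compensated_genes_flagged_above(self):
        rng = np.random.default_rng(7)
        ann = _ann_from_positions(np.arange(120) * 1000)
        comp, unc = ann.gene_ids[:60], ann.gene_ids[60:]
        labels = self._labels_from_sets(ann, comp, unc)
        enrich = pd.Series(
            np.r_[rng.normal(0.8, 0.1, 60), rng.normal(0.2, 0.1, 60)],
            index=ann.gene_ids)
        out = ec.h4k16ac_compare(labels, enrich, ann, n_boot=300, seed=2).iloc[0]
        assert out["compensated_above"] and not out["compensated_below"]

    def test_depleted_compensated_genes_flagged_below(self):
        rng = np.random.default_rng(8)
        ann = _ann_from_positions(np.arange(120) * 1000)
        comp, unc = ann.gene_ids[:40], ann.gene_ids[40:]
        labels = self._labels_from_sets(ann, comp, unc)
        enrich = pd.Series(
            np.r_[rng.normal(0.1, 0.05, 40), rng.normal(0.6, 0.1, 80)],
            index=ann.gene_ids)
        out = ec.h4k16ac_compare(labels, enrich, ann, n_boot=300, seed=3).iloc[0]
        assert out["compensated_below"] and not out["compensated_above"]

    def test_empty_label_gives_na(self):
        ann = _ann_from_positions(np.arange(10) * 1000)
        labels = self._labels_from_sets(ann, ann.gene_ids, [])
        enrich = pd.Series(0.4, index=ann.gene_ids)
        out = ec.h4k16ac_compare(labels, enrich, ann, n_boot=100, seed=4).iloc[0]
        assert np.isnan(out["uncompensated_mean"])
        assert not out["compensated_above"]


class TestCompensationLabels:
    def test_threshold_partition(self):
        frame = pd.DataFrame({
            "female_mean": [10, 10, 10, 3], "male_mean": [10, 5, 8, 1],
            "ratio": [1.0, 2.0, 1.25, np.nan],
            "included": [True, True, True, False]},
            index=["a", "b", "c", "d"])
        labels = ec.label_compensation(ec.BiasTable(frame, stage=5))
        assert list(labels.genes("compensated")) == ["a", "c"]
        assert list(labels.genes("uncompensated")) == ["b"]
        assert list(labels.genes("excluded")) == ["d"]
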