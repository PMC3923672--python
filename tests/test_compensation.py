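"""Bootstrap machinery, onset-of-compensation detection, neo-allele analyses."""

import warnings

import numpy as np
import pandas as pd
import pytest

import embryocomp as ec
from embryocomp.types import STAGES


def _onset_report(cfg, n_boot=500, seed=0):
    expr, allele, sheet, ann, truth = ec.simulate_experiment(cfg)
    norm = ec.normalize_autosomal(expr, ann)
    tl = ec.call_transcript_level(norm, sheet)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ec.maternal_allele_onset(allele, norm, sheet, ann, tl,
                                        n_boot=n_boot, seed=seed)


class TestBootstrapMean:
    def test_degenerate_constant_sample(self):
        res = ec.bootstrap_mean([5.0, 5.0, 5.0], n_boot=200, seed=1)
        assert (res.point_estimate, res.ci_low, res.ci_high) == (5.0, 5.0, 5.0)

    def test_single_value(self):
        res = ec.bootstrap_mean([7.5], n_boot=100, seed=1)
        assert res.ci_low == res.ci_high == 7.5

    def test_identical_seed_identical_ci(self):
        vals = np.random.default_rng(3).normal(size=40)
        a = ec.bootstrap_mean(vals, n_boot=500, seed=11)
        b = ec.bootstrap_mean(vals, n_boot=500, seed=11)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_empty_input_rejected(self):
        with pytest.raises(ec.ValidationError):
            ec.bootstrap_mean([], n_boot=10, seed=0)

    def test_ci_brackets_point_estimate(self):
        vals = np.random.default_rng(9).lognormal(0, 1, 30)
        res = ec.bootstrap_mean(vals, n_boot=1000, seed=2)
        assert res.ci_low <= res.point_estimate <= res.ci_high


class TestOnsetDetection:
    def test_step_trajectory_recovered_on_x_not_autosomes(self):
        traj = {s: (2.0 if s >= 6 else 1.0) for s in STAGES}
        cfg = ec.config_with(ec.default_config("pse_like", seed=23),
                             n_genes_per_chromosome={"2": 300, "4": 100, "XL": 800},
                             compensation_trajectory=traj)
        rep = _onset_report(cfg)
        assert rep.onset_stage["XL"] == 6
        assert rep.onset_stage["autosome"] is None

    def test_null_trajectory_flags_nothing(self):
        cfg = ec.config_with(ec.default_config("pse_like", seed=29),
                             compensation_trajectory={s: 1.0 for s in STAGES})
        rep = _onset_report(cfg)
        usable = rep.table[~rep.table["low_power"]]
        assert not usable["significant"].any()

    def test_species_delay_shifts_onset_one_stage(self):
        """The delayed profile reaches significance one stage later."""
        pse = _onset_report(ec.default_config("pse_like", seed=31), seed=1)
        mir = _onset_report(ec.default_config("mir_like", seed=31), seed=1)
        pse_onset = min(v for k, v in pse.onset_stage.items()
                        if k in ("XL", "XR") and v is not None)
        mir_onset = min(v for k, v in mir.onset_stage.items()
                        if k in ("XL", "XR") and v is not None)
        assert mir_onset == pse_onset + 1

    def test_full_compensation_ratio_two_at_final_stage(self):
        rep = _onset_report(ec.default_config("pse_like", seed=37), seed=2)
        cell = rep.cell("XL", 8)
        assert cell["ratio"] == pytest.approx(2.0, abs=0.15)
        assert cell["significant"]

    def test_requires_transcript_level_calls(self, pse_sim):
        as_calls = ec.call_allele_specific(pse_sim.norm, pse_sim.fractions,
                                           pse_sim.sheet)
        with pytest.raises(ValueError, match="transcript_level"):
            ec.maternal_allele_onset(pse_sim.allele, pse_sim.norm, pse_sim.sheet,
                                     pse_sim.ann, as_calls)


class TestZygoticFractionCompare:
    def test_identical_groups_unflagged(self):
        rng = np.random.default_rng(5)
        z = {s: rng.uniform(0, 1, 200) for s in range(3, 9)}
        out = ec.zygotic_fraction_compare(z, z, n_boot=300, seed=3)
        assert not out["a_outside_b"].any()
        assert not out["b_outside_a"].any()

    def test_delayed_species_flagged_early_not_late(self):
        """A one-stage activation delay separates early-stage means, which
        re-converge once both species are fully zygotic."""
        base = ec.default_config("pse_like", seed=41)
        _, _, _, _, truth = ec.simulate_experiment(base)
        shifted = truth.genes.copy()
        zyg = shifted["is_zygotic"]
        shifted.loc[zyg, "onset_stage"] = np.minimum(
            shifted.loc[zyg, "onset_stage"] + 1, 8)

        def z_by_stage(cfg, genes=None):
            _, allele, sheet, _, _ = ec.simulate_experiment(cfg, gene_params=genes)
            fr = ec.allele_fractions(allele)
            from embryocomp.preprocess import per_gene_zygotic_fraction
            return {s: per_gene_zygotic_fraction(fr, sheet, s).to_numpy()
                    for s in STAGES}

        out = ec.zygotic_fraction_compare(
            z_by_stage(base, truth.genes),
            z_by_stage(ec.config_with(base, seed=43), shifted),
            n_boot=400, seed=5)
        out = out.set_index("stage")
        early = out.loc[[3, 4]]
        late = out.loc[[7, 8]]
        assert (early["a_outside_b"] | early["b_outside_a"]).all()
        assert not (late["a_outside_b"] | late["b_outside_a"]).any()

    def test_large_gap_flags_are_mutual(self):
        rng = np.random.default_rng(8)
        a = {5: rng.uniform(0.0, 0.2, 300)}
        b = {5: rng.uniform(0.6, 1.0, 300)}
        out = ec.zygotic_fraction_compare(a, b, n_boot=300, seed=9).iloc[0]
        assert out["a_outside_b"] and out["b_outside_a"]


class TestNeoPartition:
    def test_levels_proportional_to_reads(self, mir_sim):
        part = ec.partition_neo_alleles(mir_sim.allele, mir_sim.ann, mir_sim.sheet)
        row = part.dropna(subset=["neoX_level"])
        row = row[(row["neoX_reads"] + row["neoY_reads"]) > 0].iloc[0]
        total = row["neoX_reads"] + row["neoY_reads"]
        assert row["neoX_level"] == pytest.approx(row["neoX_reads"] / total)

    def test_broken_orf_genes_with_transcription_retained(self, mir_sim):
        part = ec.partition_neo_alleles(mir_sim.allele, mir_sim.ann, mir_sim.sheet)
        orf = mir_sim.ann.frame["neoY_orf"].reindex(part["gene_id"]).to_numpy()
        broken = part[(orf == "broken") & (part["neoY_reads"] > 0)]
        assert len(broken) > 0  # transcripts are produced regardless of ORF state

    def test_zero_retention_gives_pure_neo_x_males(self):
        cfg = ec.config_with(ec.default_config("mir_like", seed=47),
                             n_genes_per_chromosome={"2": 80, "3": 150},
                             neoY_silenced_fraction=1.0)
        _, allele, sheet, ann, truth = ec.simulate_experiment(cfg)
        part = ec.partition_neo_alleles(allele, ann, sheet)
        measured = part.dropna(subset=["neoY_reads"])
        assert (measured["neoY_reads"] == 0).all()

    def test_genes_without_neo_snps_keep_combined_totals(self, mir_sim):
        part = ec.partition_neo_alleles(mir_sim.allele, mir_sim.ann, mir_sim.sheet)
        unpartitioned = part[part["neoX_reads"].isna()]
        assert len(unpartitioned) > 0
        assert (unpartitioned["combined_reads"] >= 0).all()


class TestOrfStratifiedBias:
    @pytest.fixture(scope="class")
    def mir_bias(self, mir_sim):
        calls = ec.call_allele_specific(mir_sim.norm, mir_sim.fractions,
                                        mir_sim.sheet)
        return ec.fm_ratio(mir_sim.norm, mir_sim.sheet, calls, 6)

    def test_orf_independent_compensation_indistinguishable(self, mir_sim, mir_bias):
        """Retention and compensation are drawn independently of ORF status,
        so the strata should not separate."""
        out = ec.orf_stratified_bias(mir_bias, mir_sim.ann, mode="combined_neoXY")
        p = out.loc[out["group"] == "intact_vs_broken", "wilcoxon_p"].iloc[0]
        assert p > 0.01

    def test_full_retention_combined_ratio_near_one(self):
        """With full neo-Y retention males carry two expressed copies, so the
        combined neo-XY ratio sits near 1 even without compensation."""
        cfg = ec.config_with(ec.default_config("mir_like", seed=53),
                             n_genes_per_chromosome={"2": 200, "4": 60, "3": 300},
                             neoY_silenced_fraction=0.0,
                             neoY_retention_beta=(1e6, 1.0),
                             compensation_trajectory={s: 1.0 for s in STAGES})
        expr, allele, sheet, ann, truth = ec.simulate_experiment(cfg)
        norm = ec.normalize_autosomal(expr, ann)
        calls = ec.call_allele_specific(norm, ec.allele_fractions(allele), sheet)
        bt = ec.fm_ratio(norm, sheet, calls, 6)
        out = ec.orf_stratified_bias(bt, ann, mode="combined_neoXY")
        for grp in ("intact", "broken"):
            mean = out.loc[out["group"] == grp, "mean_ratio"].iloc[0]
            assert mean == pytest.approx(1.0, abs=0.1)

    def test_neo_x_only_mode_reveals_hemizygous_bias(self, mir_sim, mir_bias):
        """Dividing male means by the neo-X read share removes the neo-Y
        contribution, pushing ratios toward the uncompensated X level."""
        part = ec.partition_neo_alleles(mir_sim.allele, mir_sim.ann, mir_sim.sheet)
        combined = ec.orf_stratified_bias(mir_bias, mir_sim.ann, mode="combined_neoXY")
        neo_only = ec.orf_stratified_bias(mir_bias, mir_sim.ann, mode="neoX_only",
                                          partition=part, sheet=mir_sim.sheet)
        m_comb = combined.loc[combined["group"] == "neo_vs_X", "median_ratio"].iloc[0]
        m_neo = neo_only.loc[neo_only["group"] == "neo_vs_X", "median_ratio"].iloc[0]
        assert m_neo > m_comb
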