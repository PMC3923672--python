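"""Bootstrap inference for the onset of dosage compensation, plus
neo-X/neo-Y partitioning and ORF-stratified sex-bias analyses.

The onset detector compares, per stage and chromosome class, the mean
transcript level attributable to the **maternal allele** in male versus
female embryos. Each sex carries exactly one maternal copy of every
chromosome, so without compensation the two means agree; when the single
male X is upregulated, the male maternal-allele mean rises above the
female's. Significance is by bootstrap CI exclusion, exactly as the study
operationalises it: a stage is flagged when the male mean falls above the
97.5% quantile of the gene-resampling bootstrap distribution of the female
mean. Genes — not embryos — are the resampling unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import AlleleFractions, allele_fractions
from .types import (
    NEO,
    X_CHROMOSOMES,
    AlleleCountTable,
    BootstrapResult,
    ExpressionTable,
    GeneAnnotation,
    SampleSheet,
    ValidationError,
)
from .bias import BiasTable, wilcoxon_compare
from .zygotic import ZygoticCalls

__all__ = ["bootstrap_mean", "bootstrap_mean_samples", "OnsetReport",
           "maternal_allele_onset", "zygotic_fraction_compare",
           "partition_neo_alleles", "orf_stratified_bias"]


def bootstrap_mean_samples(values, n_boot: int = 1000,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """The ``n_boot`` resampled means (resampling with replacement)."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValidationError("cannot bootstrap an empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    return v[idx].mean(axis=1)


def bootstrap_mean(values, n_boot: int = 1000, seed: int = 0) -> BootstrapResult:
    """Mean with an empirical 95% CI from ``n_boot`` resampled means."""
    v = np.asarray(values, dtype=float)
    means = bootstrap_mean_samples(v, n_boot=n_boot, seed=seed)
    lo, hi = np.percentile(means, [2.5, 97.5])
    point = float(v.mean())
    return BootstrapResult(point, float(min(lo, point)), float(max(hi, point)),
                           n_boot, seed if isinstance(seed, int) else -1)


@dataclass
class OnsetReport:
    """Per (chromosome class, stage) maternal-allele comparison.

    ``table`` columns: class, stage, n_genes, male_mean, female_mean,
    male_ci_low/high, female_ci_low/high, ratio (male/female), significant
    (male mean above the female 97.5% quantile), low_power.
    ``onset_stage`` maps each class to its earliest significant stage (NA if
    none).
    """

    table: pd.DataFrame
    onset_stage: dict[str, int | None]

    def cell(self, cls: str, stage: int) -> pd.Series:
        t = self.table
        return t[(t["class"] == cls) & (t["stage"] == stage)].iloc[0]


def _chromosome_class(ann: GeneAnnotation, species: str) -> pd.Series:
    """XL / XR kept separate, autosomes pooled; chr3 is 'neo' only in mir_like."""
    chrom = ann.chromosome
    cls = pd.Series("autosome", index=chrom.index)
    cls[chrom.isin(X_CHROMOSOMES)] = chrom[chrom.isin(X_CHROMOSOMES)]
    if species == "mir_like":
        cls[chrom == NEO] = "neo"
    return cls


def maternal_allele_onset(allele: AlleleCountTable, expr: ExpressionTable,
                          sheet: SampleSheet, ann: GeneAnnotation,
                          zygotic_calls: ZygoticCalls,
                          n_boot: int = 1000, seed: int = 0,
                          min_genes: int = 10,
                          fractions: AlleleFractions | None = None) -> OnsetReport:
    """Detect the stage at which male maternal-allele levels exceed female.

    Uses transcript-level zygotic calls (genes without maternal deposition),
    so the maternal allele measures zygotic transcription from the maternal
    chromosome copy. Levels are per-SNP maternal read counts scaled by the
    sample's autosomal normalization factor, making the sexes comparable.
    Autosomes are expected non-significant at every stage.
    """
    if zygotic_calls.definition != "transcript_level":
        raise ValueError("maternal_allele_onset requires transcript_level calls "
                         "(the allele-specific definition would be circular here)")
    if fractions is None:
        fractions = allele_fractions(allele)
    zyg = set(zygotic_calls.genes_at(0))
    species = sheet.frame["species"].iloc[0]
    cls = _chromosome_class(ann, species)
    scale = (expr.scale_factors if expr.scale_factors is not None
             else pd.Series(1.0, index=sheet.sample_ids))

    f = fractions.frame
    genes = f.index.get_level_values("gene_id")
    samples = f.index.get_level_values("sample_id")
    level = f["maternal_per_snp"] * scale.reindex(samples).to_numpy()
    keep = genes.isin(zyg)
    tidy = pd.DataFrame({
        "gene_id": genes[keep],
        "level": level.to_numpy()[keep],
        "stage": sheet.frame["stage"].reindex(samples[keep]).to_numpy(),
        "sex": sheet.frame["sex"].reindex(samples[keep]).to_numpy(),
        "class": cls.reindex(genes[keep]).to_numpy(),
    }).dropna(subset=["level"])

    rng = np.random.default_rng(seed)
    rows = []
    for (c, stage), g in tidy.groupby(["class", "stage"]):
        per_gene = g.pivot_table(index="gene_id", columns="sex",
                                 values="level", aggfunc="mean")
        if "male" not in per_gene or "female" not in per_gene:
            continue
        per_gene = per_gene.dropna()
        n = len(per_gene)
        if n == 0:
            continue
        low_power = n < min_genes
        if low_power:
            warnings.warn(f"class {c} stage {stage}: only {n} zygotic genes")
        f_ci = bootstrap_mean(per_gene["female"], n_boot=n_boot, seed=rng)
        m_ci = bootstrap_mean(per_gene["male"], n_boot=n_boot, seed=rng)
        male_mean, female_mean = m_ci.point_estimate, f_ci.point_estimate
        rows.append({
            "class": c, "stage": int(stage), "n_genes": n,
            "male_mean": male_mean, "female_mean": female_mean,
            "male_ci_low": m_ci.ci_low, "male_ci_high": m_ci.ci_high,
            "female_ci_low": f_ci.ci_low, "female_ci_high": f_ci.ci_high,
            "ratio": male_mean / female_mean if female_mean > 0 else np.nan,
            "significant": bool(male_mean > f_ci.ci_high),
            "low_power": low_power,
        })
    table = pd.DataFrame(rows).sort_values(["class", "stage"]).reset_index(drop=True)
    onset = {}
    for c, g in table.groupby("class"):
        # low-power cells stay visible in the table but cannot declare onset
        sig = g.loc[g["significant"] & ~g["low_power"], "stage"]
        onset[c] = int(sig.min()) if len(sig) else None
    return OnsetReport(table=table, onset_stage=onset)


def zygotic_fraction_compare(z_by_stage_a: dict[int, np.ndarray],
                             z_by_stage_b: dict[int, np.ndarray],
                             n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Compare per-stage mean zygotic fractions between two timecourses.

    ``z_by_stage_*`` map stage -> per-gene z values. For each shared stage the
    mean and bootstrap CI is computed per group, and a group is flagged when
    its mean lies outside the other group's CI.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for stage in sorted(set(z_by_stage_a) & set(z_by_stage_b)):
        a = np.asarray(z_by_stage_a[stage], dtype=float)
        b = np.asarray(z_by_stage_b[stage], dtype=float)
        if len(a) == 0 or len(b) == 0:
            continue
        ci_a = bootstrap_mean(a, n_boot=n_boot, seed=rng)
        ci_b = bootstrap_mean(b, n_boot=n_boot, seed=rng)
        rows.append({
            "stage": stage,
            "mean_a": ci_a.point_estimate, "ci_low_a": ci_a.ci_low, "ci_high_a": ci_a.ci_high,
            "mean_b": ci_b.point_estimate, "ci_low_b": ci_b.ci_low, "ci_high_b": ci_b.ci_high,
            "a_outside_b": not ci_b.contains(ci_a.point_estimate),
            "b_outside_a": not ci_a.contains(ci_b.point_estimate),
            "n_a": len(a), "n_b": len(b),
        })
    return pd.DataFrame(rows)


def partition_neo_alleles(allele: AlleleCountTable, ann: GeneAnnotation,
                          sheet: SampleSheet) -> pd.DataFrame:
    """Split male neo-XY gene reads into neo-X and neo-Y components.

    Returns a tidy frame (gene_id, sample_id, neoX_reads, neoY_reads,
    neoX_level, neoY_level, combined_reads) over male samples and neo-XY
    genes. Levels are the within-gene proportions of the partitionable reads.
    Genes without neo-divergence SNPs have NaN components but keep their
    combined (maternal+paternal) totals, so combined neo-XY analyses retain
    them.
    """
    if not allele.has_neo_columns:
        raise ValidationError("allele table carries no neo-X/neo-Y columns")
    males = set(sheet.samples(sex="male"))
    neo_genes = set(ann.genes_on(NEO))
    f = allele.frame
    idx = f.index
    mask = (idx.get_level_values("gene_id").isin(neo_genes)
            & idx.get_level_values("sample_id").isin(males))
    sub = f[mask]
    total_neo = sub["neoX_reads"] + sub["neoY_reads"]
    with np.errstate(invalid="ignore", divide="ignore"):
        x_level = np.where(total_neo > 0, sub["neoX_reads"] / total_neo, np.nan)
        y_level = np.where(total_neo > 0, sub["neoY_reads"] / total_neo, np.nan)
    out = pd.DataFrame({
        "neoX_reads": sub["neoX_reads"],
        "neoY_reads": sub["neoY_reads"],
        "neoX_level": x_level,
        "neoY_level": y_level,
        "combined_reads": sub["maternal_reads"] + sub["paternal_reads"],
    }, index=sub.index)
    return out.reset_index()


def _neo_x_fraction(partition: pd.DataFrame, sheet: SampleSheet,
                    stage: int) -> pd.Series:
    """Per-gene mean neo-X share of male neo-XY reads at one stage."""
    stages = sheet.frame["stage"].reindex(partition["sample_id"]).to_numpy()
    sub = partition[stages == stage]
    return sub.groupby("gene_id")["neoX_level"].mean()


def orf_stratified_bias(bias: BiasTable, ann: GeneAnnotation,
                        mode: str = "combined_neoXY",
                        partition: pd.DataFrame | None = None,
                        sheet: SampleSheet | None = None,
                        min_stratum: int = 5) -> pd.DataFrame:
    """Sex-bias of neo-XY genes stratified by neo-Y ORF status.

    ``mode="combined_neoXY"`` uses the plain expression F:M ratio (male reads
    include both the neo-X and neo-Y copy). ``mode="neoX_only"`` rescales each
    gene's male mean by its neo-X read share (requires ``partition`` and
    ``sheet``), isolating compensation of the male neo-X itself.

    Returns one row per stratum (intact / broken) plus comparison rows with
    Wilcoxon p-values: intact vs broken, and each stratum vs the older X
    chromosomes (XL+XR).
    """
    if mode not in ("combined_neoXY", "neoX_only"):
        raise ValueError(f"unknown mode: {mode}")
    ratios = bias.included_ratios()
    neo_genes = ann.genes_on(NEO)
    neo_ratios = ratios[ratios.index.isin(neo_genes)]
    if mode == "neoX_only":
        if partition is None or sheet is None:
            raise ValueError("neoX_only mode requires partition and sheet")
        share = _neo_x_fraction(partition, sheet, bias.stage)
        share = share.reindex(neo_ratios.index).dropna()
        neo_ratios = (neo_ratios.reindex(share.index) / share).dropna()
    orf = ann.frame["neoY_orf"].reindex(neo_ratios.index)
    x_ratios = ratios[ratios.index.isin(ann.genes_on(X_CHROMOSOMES))]

    rows = []
    strata = {}
    for status in ("intact", "broken"):
        vals = neo_ratios[orf == status]
        strata[status] = vals
        if len(vals) < min_stratum:
            warnings.warn(f"ORF stratum {status!r} has only {len(vals)} genes")
        rows.append({"stage": bias.stage, "mode": mode, "group": status,
                     "n_genes": len(vals),
                     "mean_ratio": float(vals.mean()) if len(vals) else np.nan,
                     "median_ratio": float(vals.median()) if len(vals) else np.nan,
                     "wilcoxon_p": np.nan, "comparison": ""})
    if len(strata["intact"]) and len(strata["broken"]):
        _, p = wilcoxon_compare(strata["intact"], strata["broken"])
        rows.append({"stage": bias.stage, "mode": mode, "group": "intact_vs_broken",
                     "n_genes": len(neo_ratios), "mean_ratio": np.nan,
                     "median_ratio": np.nan, "wilcoxon_p": p,
                     "comparison": "intact vs broken"})
    if len(neo_ratios) and len(x_ratios):
        _, p = wilcoxon_compare(neo_ratios, x_ratios)
        rows.append({"stage": bias.stage, "mode": mode, "group": "neo_vs_X",
                     "n_genes": len(neo_ratios), "mean_ratio": float(neo_ratios.mean()),
                     "median_ratio": float(neo_ratios.median()), "wilcoxon_p": p,
                     "comparison": "neo vs XL+XR"})
    return pd.DataFrame(rows)
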