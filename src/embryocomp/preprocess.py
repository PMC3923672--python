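"""Normalization, per-gene allele aggregation and zygotic-fraction estimation.

The zygotic fraction of a gene's transcript pool is estimated from the
paternal read fraction *p*: maternally deposited transcript carries only
maternal alleles, while zygotic transcript from a biallelic autosomal (or
female X) locus is split evenly between the alleles, so doubling *p* recovers
the zygotic share. The estimate is clipped to [0, 1] — under sampling noise
2p can exceed 1 although a transcript fraction cannot.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import (
    REFERENCE_AUTOSOMES,
    AlleleCountTable,
    ExpressionTable,
    GeneAnnotation,
    SampleSheet,
    ValidationError,
)

__all__ = ["normalize_autosomal", "allele_fractions", "zygotic_fraction",
           "snp_coverage_summary", "AlleleFractions"]


class AlleleFractions:
    """Per (gene, sample) per-SNP allele levels and paternal fraction.

    ``frame`` carries ``maternal_per_snp``, ``paternal_per_snp`` (combined
    reads divided by the number of SNPs observed), the paternal fraction ``p``
    and the clipped zygotic-fraction estimate ``z = min(2p, 1)``. Rows where
    no allele reads were observed have ``p`` and ``z`` missing (NaN), never 0.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def per_sample(self, column: str) -> pd.DataFrame:
        """Pivot one column to a gene x sample matrix."""
        return self.frame[column].unstack("sample_id")


def normalize_autosomal(expr: ExpressionTable, ann: GeneAnnotation,
                        reference_chromosomes=REFERENCE_AUTOSOMES,
                        T_ref: float | None = None,
                        mode: str = "autosomal") -> ExpressionTable:
    """Scale each sample so reference-autosome totals are constant.

    Sample *j* is multiplied by ``s_j = T_ref / sum_{g in ref} RPKM_gj`` where
    ``T_ref`` defaults to the across-sample mean reference total; afterwards
    every per-sample reference total equals ``T_ref`` (relative tolerance
    1e-9). ``mode="total_reads"`` skips rescaling (returns a normalized-flagged
    copy with unit factors), matching the observation that the choice of
    normalization does not move the X-to-autosome comparisons.
    """
    if mode == "total_reads":
        out = ExpressionTable(expr.values.copy(), normalized=True,
                              normalization_reference=None)
        out.scale_factors = pd.Series(1.0, index=expr.values.columns)
        return out
    ref_genes = ann.genes_on(set(reference_chromosomes))
    ref_genes = ref_genes.intersection(expr.values.index)
    if len(ref_genes) == 0:
        raise ValidationError("no reference-chromosome genes in expression table")
    totals = expr.values.loc[ref_genes].sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero autosomal total for sample(s): {list(zero[:5])}")
    if T_ref is None:
        T_ref = float(totals.mean())
    factors = T_ref / totals
    out = ExpressionTable(expr.values.mul(factors, axis=1), normalized=True,
                          normalization_reference=T_ref)
    out.scale_factors = factors
    return out


def allele_fractions(allele: AlleleCountTable) -> AlleleFractions:
    """Aggregate SNP-level counts to per-gene per-SNP means and fractions.

    Maternal and paternal reads for each gene/sample are combined and divided
    by the number of SNPs observed. The paternal fraction is undefined
    (missing) when no allele reads were seen.
    """
    f = allele.frame
    n = f["n_snps_observed"].to_numpy(dtype=float)
    total = (f["maternal_reads"] + f["paternal_reads"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m_per = np.where(n > 0, f["maternal_reads"].to_numpy() / n, np.nan)
        p_per = np.where(n > 0, f["paternal_reads"].to_numpy() / n, np.nan)
        p = np.where(total > 0, f["paternal_reads"].to_numpy() / total, np.nan)
    out = pd.DataFrame({
        "maternal_per_snp": m_per,
        "paternal_per_snp": p_per,
        "p": p,
        "z": np.minimum(2 * p, 1.0),
    }, index=f.index)
    return AlleleFractions(out)


def zygotic_fraction(fractions: AlleleFractions, sheet: SampleSheet,
                     ann: GeneAnnotation | None = None,
                     double_then_average: bool = True) -> pd.DataFrame:
    """Per-stage mean zygotic fraction, from female embryos only.

    Female embryos are used so that the X chromosomes contribute paternal
    reads. Per gene and sample ``z = min(2p, 1)``; z is averaged across
    replicate embryos within a stage, then across genes, optionally broken
    out per chromosome class (when an annotation is supplied).

    ``double_then_average=False`` averages p across embryos first and doubles
    the stage-level mean instead (the alternative reading).

    Returns a tidy frame: stage, chromosome ('all' when no annotation),
    mean_z, n_genes.
    """
    females = sheet.samples(sex="female")
    if len(females) == 0:
        raise ValidationError("no female samples available")
    f = fractions.frame
    mask = f.index.get_level_values("sample_id").isin(set(females))
    sub = f[mask]
    stage_of = sheet.frame["stage"]
    stages = stage_of.reindex(sub.index.get_level_values("sample_id")).to_numpy()
    genes = sub.index.get_level_values("gene_id")

    col = "z" if double_then_average else "p"
    per_gene_stage = (sub[col].groupby([genes, stages]).mean()
                      .rename_axis(["gene_id", "stage"]))
    if not double_then_average:
        per_gene_stage = np.minimum(2 * per_gene_stage, 1.0)

    records = []
    tidy = per_gene_stage.reset_index(name="z").dropna(subset=["z"])
    groups = [("all", tidy)]
    if ann is not None:
        tidy = tidy.assign(chromosome=ann.chromosome.reindex(tidy["gene_id"]).to_numpy())
        groups = list(tidy.groupby("chromosome"))
    for chrom, g in groups:
        for stage, gg in g.groupby("stage"):
            records.append({"stage": int(stage), "chromosome": chrom,
                            "mean_z": float(gg["z"].mean()), "n_genes": len(gg)})
    present = {int(s) for s in stage_of.reindex(females).unique()}
    missing = set(sheet.stages_present()) - present
    if missing:
        warnings.warn(f"no female samples at stage(s) {sorted(missing)}; omitted")
    return pd.DataFrame(records).sort_values(["chromosome", "stage"]).reset_index(drop=True)


def per_gene_zygotic_fraction(fractions: AlleleFractions, sheet: SampleSheet,
                              stage: int) -> pd.Series:
    """Per-gene z at one stage (female embryos, replicate-averaged)."""
    females = set(sheet.samples(stage=stage, sex="female"))
    f = fractions.frame
    mask = f.index.get_level_values("sample_id").isin(females)
    genes = f.index.get_level_values("gene_id")[mask]
    return f.loc[mask, "z"].groupby(genes).mean().dropna()


def snp_coverage_summary(expr: ExpressionTable, allele: AlleleCountTable,
                         ann: GeneAnnotation) -> pd.DataFrame:
    """Proportion of expressed genes with SNP information, per chromosome.

    A gene counts as expressed when it has at least one read anywhere in the
    dataset; the proportion is SNP-covered expressed genes over expressed
    genes (NA for chromosomes with no expressed genes).
    """
    expressed = expr.values.index[(expr.values > 0).any(axis=1)]
    covered = set(allele.frame.index.get_level_values("gene_id"))
    records = []
    for chrom in ann.chromosome.unique():
        on = ann.genes_on(chrom).intersection(expressed)
        n_cov = sum(1 for g in on if g in covered)
        prop = n_cov / len(on) if len(on) else np.nan
        records.append({"chromosome": chrom, "n_expressed": len(on),
                        "n_with_snps": n_cov, "proportion": prop})
    return pd.DataFrame(records).set_index("chromosome")
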