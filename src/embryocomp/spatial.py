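"""Spatial clustering of compensated genes, HAS proximity and H4K16ac tests.

The clustering statistic is the mean distance from each gene in a set to its
nearest neighbour in the same set. Because zygotically transcribed genes are
themselves clustered along the chromosome, the null distribution must be
drawn from zygotic genes (resampled without replacement); drawing from all
genes reproduces the confounded control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import BiasTable, wilcoxon_compare
from .compensation import bootstrap_mean
from .types import GeneAnnotation, ValidationError
from .zygotic import ZygoticCalls

__all__ = ["CompensationLabels", "label_compensation", "nn_distance_stat",
           "clustering_test", "has_proximity_test", "h4k16ac_compare"]

DEFAULT_COMPENSATED_CUTOFF = 1.5


@dataclass
class CompensationLabels:
    """Per-gene compensated / uncompensated / excluded labels at one stage.

    A gene is compensated when its F:M ratio is below ``threshold`` (default
    1.5), uncompensated above it; genes failing the >5 RPKM inclusion rule
    are excluded.
    """

    labels: pd.Series
    stage: int
    threshold: float = DEFAULT_COMPENSATED_CUTOFF

    def genes(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def label_compensation(bias: BiasTable,
                       threshold: float = DEFAULT_COMPENSATED_CUTOFF,
                       ) -> CompensationLabels:
    """Label genes by the operational compensated definition (ratio < 1.5)."""
    r = bias.frame["ratio"]
    labels = pd.Series("excluded", index=bias.frame.index)
    labels[r < threshold] = "compensated"
    labels[r > threshold] = "uncompensated"
    return CompensationLabels(labels=labels, stage=bias.stage, threshold=threshold)


def nn_distance_stat(positions) -> float:
    """Mean distance (bp) from each position to its nearest other position.

    Positions are gene start coordinates on one chromosome. Undefined for
    fewer than two genes.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    if len(pos) < 2:
        raise ValidationError("nearest-neighbour statistic needs >= 2 positions")
    gaps = np.diff(pos)
    left = np.concatenate([[np.inf], gaps])
    right = np.concatenate([gaps, [np.inf]])
    return float(np.minimum(left, right).mean())


def clustering_test(labels: CompensationLabels, ann: GeneAnnotation,
                    zygotic_calls: ZygoticCalls | None = None,
                    null_universe: str = "zygotic",
                    n_reps: int = 999, seed: int = 0,
                    position: str = "start") -> pd.DataFrame:
    """Are compensated (or uncompensated) genes closer together than chance?

    For each chromosome and label, compares the observed mean
    nearest-neighbour distance to ``n_reps`` draws of equally many genes
    (without replacement) from the null universe on the same chromosome:
    zygotic genes at this stage (default, requires ``zygotic_calls``) or all
    annotated genes. The empirical p-value is the left-tail fraction with the
    add-one correction, p = (1 + #{null <= observed}) / (n_reps + 1), so
    p is never zero.
    """
    if null_universe not in ("zygotic", "all"):
        raise ValueError(f"unknown null universe: {null_universe}")
    if null_universe == "zygotic":
        if zygotic_calls is None:
            raise ValueError("zygotic null universe requires zygotic_calls")
        universe = pd.Index(zygotic_calls.genes_at(labels.stage))
    else:
        universe = ann.gene_ids
    pos_col = ann.frame["start"] if position == "start" else (
        (ann.frame["start"] + ann.frame["end"]) // 2)
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in sorted(ann.chromosome.unique()):
        chrom_genes = ann.genes_on(chrom)
        null_pool = pos_col.reindex(universe.intersection(chrom_genes)).to_numpy(float)
        for label in ("compensated", "uncompensated"):
            genes = labels.genes(label).intersection(chrom_genes)
            if len(genes) < 2:
                continue
            if len(genes) > len(null_pool):
                raise ValidationError(
                    f"label set ({len(genes)}) larger than null universe "
                    f"({len(null_pool)}) on chromosome {chrom}")
            observed = nn_distance_stat(pos_col.reindex(genes).to_numpy(float))
            null = np.empty(n_reps)
            k = len(genes)
            for i in range(n_reps):
                draw = rng.choice(null_pool, size=k, replace=False)
                null[i] = nn_distance_stat(draw)
            p = (1 + np.sum(null <= observed)) / (n_reps + 1)
            rows.append({"chromosome": chrom, "stage": labels.stage,
                         "label": label, "n_genes": k,
                         "observed_mean_nn": observed,
                         "null_mean": float(null.mean()), "p": float(p)})
    return pd.DataFrame(rows)


def _distance_to_intervals(points: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Min distance from each point to any [start, end) interval (0 inside)."""
    starts = intervals["start"].to_numpy(float)
    ends = intervals["end"].to_numpy(float)
    d = np.maximum.reduce([starts[None, :] - points[:, None],
                           points[:, None] - ends[None, :],
                           np.zeros((len(points), len(starts)))])
    return d.min(axis=1)


def has_proximity_test(bias: BiasTable, has_intervals: pd.DataFrame,
                       ann: GeneAnnotation, per_chromosome: bool = False,
                       ) -> pd.DataFrame:
    """Is sex bias associated with proximity to MSL high-affinity sites?

    Gene distance is from the gene start to the nearest HAS interval on the
    same chromosome (0 when inside one). Genes in the lower quartile of
    distances (ties included in the lower group) are compared to the upper
    three quartiles with a two-sided Wilcoxon test on their F:M ratios.
    Pooled over chromosomes carrying HAS by default.
    """
    ratios = bias.included_ratios()
    chrom = ann.chromosome.reindex(ratios.index)
    records = []
    has_chroms = sorted(set(has_intervals["chromosome"]))
    groups = ([(c, ratios[chrom == c]) for c in has_chroms] if per_chromosome
              else [("pooled", ratios[chrom.isin(has_chroms)])])
    for name, r in groups:
        if len(r) < 8:
            warnings.warn(f"{name}: fewer than 8 genes with ratios; skipped")
            continue
        dists = np.empty(len(r))
        for i, g in enumerate(r.index):
            c = chrom[g]
            iv = has_intervals[has_intervals["chromosome"] == c]
            if len(iv) == 0:
                dists[i] = np.nan
                continue
            dists[i] = _distance_to_intervals(
                np.array([ann.frame.at[g, "start"]], float), iv)[0]
        ok = ~np.isnan(dists)
        r, dists = r[ok], dists[ok]
        q25 = np.percentile(dists, 25)
        near = dists <= q25
        if near.all() or not near.any() or np.all(dists == dists[0]):
            warnings.warn(f"{name}: HAS distances degenerate; test undefined")
            continue
        _, p = wilcoxon_compare(r[near], r[~near])
        records.append({"group": name, "stage": bias.stage,
                        "n_near": int(near.sum()), "n_far": int((~near).sum()),
                        "mean_ratio_near": float(r[near].mean()),
                        "mean_ratio_far": float(r[~near].mean()),
                        "wilcoxon_p": p})
    return pd.DataFrame(records)


def h4k16ac_compare(labels: CompensationLabels, enrichment: pd.Series,
                    ann: GeneAnnotation, chromosomes=None,
                    n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Compare mean H4K16ac enrichment of compensated vs uncompensated genes.

    Per chromosome: mean per-gene enrichment for each label with a
    gene-resampling bootstrap CI, and exclusion flags in both directions —
    a label's mean falling above the other's 97.5% quantile or below its
    2.5% quantile.
    """
    rng = np.random.default_rng(seed)
    if chromosomes is None:
        chromosomes = sorted(ann.chromosome.unique())
    rows = []
    for chrom in chromosomes:
        chrom_genes = ann.genes_on(chrom)
        cis = {}
        for label in ("compensated", "uncompensated"):
            genes = labels.genes(label).intersection(chrom_genes)
            vals = enrichment.reindex(genes).dropna()
            cis[label] = (bootstrap_mean(vals, n_boot=n_boot, seed=rng)
                          if len(vals) else None)
        comp, unc = cis["compensated"], cis["uncompensated"]
        row = {"chromosome": chrom, "stage": labels.stage}
        for label, ci in cis.items():
            row[f"{label}_mean"] = ci.point_estimate if ci else np.nan
            row[f"{label}_ci_low"] = ci.ci_low if ci else np.nan
            row[f"{label}_ci_high"] = ci.ci_high if ci else np.nan
        row["compensated_above"] = bool(comp and unc
                                        and comp.point_estimate > unc.ci_high)
        row["compensated_below"] = bool(comp and unc
                                        and comp.point_estimate < unc.ci_low)
        rows.append(row)
    return pd.DataFrame(rows)
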