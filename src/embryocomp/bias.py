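"""Female:male expression ratios, sex-bias classes and between-group tests.

The central quantity is the per-gene ratio of female to male mean RPKM at a
stage, computed only for genes whose means in *both* sexes exceed 5 RPKM (so
no pseudocounts are needed) and that are zygotically transcribed under the
supplied call set. An uncompensated X-linked gene sits near 2 (two female
copies, one male copy); a fully compensated gene sits near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    BootstrapResult,
    ExpressionTable,
    GeneAnnotation,
    SampleSheet,
    ValidationError,
)
from .zygotic import ZygoticCalls

__all__ = ["BiasTable", "fm_ratio", "classify_bias", "chisq_cutoff_compare",
           "chisq_cutoff_grid", "wilcoxon_compare", "stage_correspondence",
           "StageCorrespondence", "BIAS_CLASSES", "DEFAULT_CUTPOINTS"]

#: class label -> (low, high] interval of the F:M ratio. Female bias above
#: 1.5 and 2.0 are the cut points the cutoff-comparison tables use; the
#: intermediate shades and the unbiased band are package defaults.
DEFAULT_CUTPOINTS = (0.8, 1.25, 1.5, 2.0)
BIAS_CLASSES = ("male_biased", "unbiased", "female_1.25_1.5", "female_1.5_2", "female_gt2")


@dataclass
class BiasTable:
    """Per-gene F:M ratios at one stage.

    ``frame`` is indexed by gene_id with columns ``female_mean``,
    ``male_mean``, ``ratio`` and ``included``; ``ratio`` is NaN for excluded
    genes.
    """

    frame: pd.DataFrame
    stage: int
    rpkm_min: float = 5.0
    cutpoints: tuple = DEFAULT_CUTPOINTS

    def included_ratios(self) -> pd.Series:
        return self.frame.loc[self.frame["included"], "ratio"]


def fm_ratio(expr: ExpressionTable, sheet: SampleSheet,
             zygotic_calls: ZygoticCalls | None, stage: int,
             rpkm_min: float = 5.0) -> BiasTable:
    """Female:male ratio of mean RPKM per gene at ``stage``.

    Restricted to genes called zygotic by ``zygotic_calls`` (at that stage for
    allele-specific calls, per gene for transcript-level calls; pass ``None``
    to skip the restriction) whose means in both sexes exceed ``rpkm_min``.
    """
    females = sheet.samples(stage=stage, sex="female")
    males = sheet.samples(stage=stage, sex="male")
    if len(females) == 0 or len(males) == 0:
        warnings.warn(f"stage {stage} lacks one sex; skipped")
        return BiasTable(pd.DataFrame(
            columns=["female_mean", "male_mean", "ratio", "included"]), stage, rpkm_min)
    f_mean = expr.values[list(females)].mean(axis=1)
    m_mean = expr.values[list(males)].mean(axis=1)
    included = (f_mean > rpkm_min) & (m_mean > rpkm_min)
    if zygotic_calls is not None:
        zyg = expr.values.index.isin(zygotic_calls.genes_at(stage))
        included &= zyg
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(included, f_mean / m_mean, np.nan)
    frame = pd.DataFrame({"female_mean": f_mean, "male_mean": m_mean,
                          "ratio": ratio, "included": included})
    return BiasTable(frame, stage=stage, rpkm_min=rpkm_min)


def classify_gene_ratios(ratios: pd.Series,
                         cutpoints: tuple = DEFAULT_CUTPOINTS) -> pd.Series:
    """Assign each ratio to a sex-bias class (partition of (0, inf))."""
    lo, mid, c15, c20 = cutpoints
    bins = [-np.inf, lo, mid, c15, c20, np.inf]
    return pd.cut(ratios, bins=bins, labels=BIAS_CLASSES, right=True)


def classify_bias(bias: BiasTable, ann: GeneAnnotation,
                  cutpoints: tuple = DEFAULT_CUTPOINTS) -> pd.DataFrame:
    """Per-chromosome proportions of genes in each sex-bias class."""
    ratios = bias.included_ratios()
    classes = classify_gene_ratios(ratios, cutpoints)
    chrom = ann.chromosome.reindex(ratios.index)
    counts = (pd.crosstab(chrom, classes)
              .reindex(columns=BIAS_CLASSES, fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    props["n_genes"] = counts.sum(axis=1)
    return props


def chisq_cutoff_compare(ratios_a, ratios_b, cutoff: float,
                         yates: bool = False) -> tuple[float, float]:
    """2x2 chi-squared test (df=1) of the proportion of genes above ``cutoff``.

    No continuity correction by default. Symmetric in group order. A warning
    is attached when an expected cell drops below 1.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be nonempty")
    table = np.array([[np.sum(a > cutoff), np.sum(a <= cutoff)],
                      [np.sum(b > cutoff), np.sum(b <= cutoff)]], dtype=float)
    if (table.sum(axis=0) == 0).any():
        # a degenerate margin: identical classification in both groups
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 1).any():
        warnings.warn("chi-squared expected cell count below 1")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def chisq_cutoff_grid(ratios_a, ratios_b,
                      cutoffs=np.arange(1.5, 2.01, 0.1),
                      yates: bool = False) -> pd.DataFrame:
    """chisq_cutoff_compare over a grid of female-bias cutoffs.

    P-values are reported unadjusted, with a Benjamini-Hochberg column added
    for completeness.
    """
    rows = []
    for c in cutoffs:
        chi2, p = chisq_cutoff_compare(ratios_a, ratios_b, float(c), yates=yates)
        rows.append({"cutoff": round(float(c), 10), "chi2": chi2, "p": p,
                     "frac_above_a": float(np.mean(np.asarray(ratios_a) > c)),
                     "frac_above_b": float(np.mean(np.asarray(ratios_b) > c))})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def wilcoxon_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when both groups have <= 10 observations and there
    are no ties; normal approximation with tie correction otherwise. Returns
    (U statistic of the first group, p). Two identical multisets give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class StageCorrespondence:
    """Spearman stage-correspondence analysis between two timecourses."""

    rho: pd.DataFrame                     # stage_a x stage_b correlations
    diagonal_ci: dict[int, BootstrapResult]
    row_p: pd.Series                      # P(best off-diagonal beats diagonal)
    n_genes: int


def _stage_mean_matrix(expr: ExpressionTable, sheet: SampleSheet) -> pd.DataFrame:
    return pd.DataFrame({s: expr.values[list(sheet.samples(stage=s))].mean(axis=1)
                         for s in sheet.stages_present()})


def _spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ra = stats.rankdata(a, axis=0)
    rb = stats.rankdata(b, axis=0)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.sqrt((ra ** 2).sum(axis=0)[:, None] * (rb ** 2).sum(axis=0)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, ra.T @ rb / denom, np.nan)


def stage_correspondence(expr_a: ExpressionTable, sheet_a: SampleSheet,
                         expr_b: ExpressionTable, sheet_b: SampleSheet,
                         gene_map: pd.DataFrame | None = None,
                         n_boot: int = 1000, seed: int = 0) -> StageCorrespondence:
    """Do morphologically matched stages have the most similar transcriptomes?

    Computes the Spearman rank correlation between per-stage mean expression
    vectors for every stage pair, a gene-resampling bootstrap CI for each
    diagonal (same-stage) correlation, and a row p-value: the fraction of
    bootstrap replicates in which the row's best off-diagonal correlation
    exceeds the diagonal one.
    """
    mat_a = _stage_mean_matrix(expr_a, sheet_a)
    mat_b = _stage_mean_matrix(expr_b, sheet_b)
    if gene_map is None:
        shared = mat_a.index.intersection(mat_b.index)
        a_ids, b_ids = shared, shared
    else:
        m = gene_map[gene_map.iloc[:, 0].isin(mat_a.index)
                     & gene_map.iloc[:, 1].isin(mat_b.index)]
        a_ids, b_ids = m.iloc[:, 0], m.iloc[:, 1]
    if len(a_ids) < 50:
        raise ValidationError(f"need >= 50 shared genes, have {len(a_ids)}")
    A = mat_a.loc[a_ids].to_numpy()
    B = mat_b.loc[b_ids].to_numpy()
    stages_a, stages_b = list(mat_a.columns), list(mat_b.columns)
    rho = _spearman_matrix(A, B)

    rng = np.random.default_rng(seed)
    n = len(A)
    diag_samples = {s: np.empty(n_boot) for s in stages_a if s in stages_b}
    beats = {s: 0 for s in diag_samples}
    for it in range(n_boot):
        idx = rng.integers(0, n, n)
        r = _spearman_matrix(A[idx], B[idx])
        for i, s in enumerate(stages_a):
            if s not in diag_samples:
                continue
            j = stages_b.index(s)
            diag_samples[s][it] = r[i, j]
            off = np.delete(r[i], j)
            if len(off) and np.nanmax(off) > r[i, j]:
                beats[s] += 1

    diagonal_ci = {}
    row_p = {}
    for i, s in enumerate(stages_a):
        if s not in diag_samples:
            continue
        j = stages_b.index(s)
        lo, hi = np.nanpercentile(diag_samples[s], [2.5, 97.5])
        diagonal_ci[s] = BootstrapResult(float(rho[i, j]), float(min(lo, rho[i, j])),
                                         float(max(hi, rho[i, j])), n_boot, seed)
        row_p[s] = beats[s] / n_boot
    return StageCorrespondence(
        rho=pd.DataFrame(rho, index=stages_a, columns=stages_b),
        diagonal_ci=diagonal_ci,
        row_p=pd.Series(row_p),
        n_genes=n)
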