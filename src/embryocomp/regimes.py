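"""Reference simulated dosage-compensation regimes.

These functions run the full pipeline — generator, normalization, zygotic
classification, ratio or maternal-allele analysis — on three canonical
chromosome-dose regimes and return the headline statistic of each:

* :func:`no_compensation_fm_ratio` — per-copy transcription equal between the
  sexes (factor 1 throughout): the mean F:M ratio over X-linked zygotic genes
  at the first zygotic stages recovers the 2:1 chromosome dose.
* :func:`half_compensated_fm_ratio` — half of zygotic X genes fully
  compensated (factor 2), half uncompensated: the late-blastoderm mean sits
  midway, at 1.5.
* :func:`full_msl_maternal_ratio` — the compensation ramp reaches factor 2 by
  the final stage: the male maternal-X allele level is twice the female's.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .bias import fm_ratio
from .compensation import maternal_allele_onset
from .preprocess import allele_fractions, normalize_autosomal
from .simulate import config_with, default_config, simulate_experiment
from .types import STAGES, X_CHROMOSOMES
from .zygotic import call_allele_specific, call_transcript_level

__all__ = ["no_compensation_fm_ratio", "half_compensated_fm_ratio",
           "full_msl_maternal_ratio"]

#: called X genes needed before a stage counts as zygotically active
_MIN_CALLED = 20


def no_compensation_fm_ratio(seed: int = 1, x_scale: int = 4) -> tuple[float, int]:
    """Mean F:M over X-linked (XL+XR) zygotic genes at the first two zygotic
    stages, mir_like karyotype with the compensation trajectory pinned at 1.

    ``x_scale`` multiplies the default X-linked gene counts to tighten the
    Monte-Carlo error of the mean. Returns (mean ratio, number of gene
    measurements pooled).
    """
    base = default_config("mir_like", seed=seed)
    genes = dict(base.n_genes_per_chromosome)
    genes["XL"] *= x_scale
    genes["XR"] *= x_scale
    cfg = config_with(base, n_genes_per_chromosome=genes,
                      compensation_trajectory={s: 1.0 for s in STAGES})
    expr, allele, sheet, ann, _ = simulate_experiment(cfg)
    norm = normalize_autosomal(expr, ann)
    calls = call_allele_specific(norm, allele_fractions(allele), sheet)
    x_genes = set(ann.genes_on(X_CHROMOSOMES))
    counts = {s: sum(g in x_genes for g in calls.genes_at(s))
              for s in calls.stages()}
    # a stage counts as zygotically active once a substantial share of the
    # eventually-called X genes are on; this keeps the barely-crossing
    # stage with a handful of early outlier genes out of "early zygotic"
    floor = max(_MIN_CALLED, 0.25 * max(counts.values()))
    stages = [s for s in sorted(counts) if counts[s] >= floor][:2]
    ratios = []
    for stage in stages:
        r = fm_ratio(norm, sheet, calls, stage).included_ratios()
        ratios.append(r[r.index.isin(x_genes)])
    pooled = pd.concat(ratios)
    return float(pooled.mean()), len(pooled)


def half_compensated_fm_ratio(seed: int = 1, n_x_genes: int = 1200) -> tuple[float, int]:
    """Mean F:M over X-linked zygotic genes at the late-blastoderm stage,
    mel_like karyotype: half of zygotic X genes at factor 2, half at 1.

    Returns (mean ratio, number of X genes measured).
    """
    cfg = default_config("mel_like", seed=seed)
    genes = dict(cfg.n_genes_per_chromosome)
    genes["XL"] = n_x_genes
    cfg = config_with(cfg, n_genes_per_chromosome=genes)
    expr, allele, sheet, ann, _ = simulate_experiment(cfg)
    norm = normalize_autosomal(expr, ann)
    calls = call_allele_specific(norm, allele_fractions(allele), sheet)
    late_blastoderm = 4  # ordinal for morphological late stage 5
    r = fm_ratio(norm, sheet, calls, late_blastoderm).included_ratios()
    rx = r[r.index.isin(set(ann.genes_on("XL")))]
    return float(rx.mean()), len(rx)


def full_msl_maternal_ratio(seed: int = 1) -> tuple[float, int]:
    """Male:female maternal-X allele level at the final stage, pse_like
    karyotype whose ramp reaches factor 2 there.

    Returns (ratio at the XL final-stage cell, number of genes in the cell).
    """
    cfg = default_config("pse_like", seed=seed)
    expr, allele, sheet, ann, _ = simulate_experiment(cfg)
    norm = normalize_autosomal(expr, ann)
    tl = call_transcript_level(norm, sheet)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = maternal_allele_onset(allele, norm, sheet, ann, tl,
                                       n_boot=1000, seed=seed)
    cell = report.cell("XL", STAGES[-1])
    return float(cell["ratio"]), int(cell["n_genes"])
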