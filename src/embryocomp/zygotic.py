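"""Zygotic-transcription calls under the two operational definitions.

* **allele_specific** — per stage and species: a gene is zygotic when its mean
  female expression exceeds ``rpkm_min`` (default 5 RPKM) *and* the paternal
  allele carries more than ``paternal_min_fraction`` (default 40%) of its
  female allele reads. Female embryos are used because males have no paternal
  X. Genes without allele data are not callable — distinct from a negative
  call.
* **transcript_level** — per gene, sex-agnostic: no maternal deposition (mean
  below ``rpkm_min`` at the first sampled stage) and mean expression above
  ``rpkm_min`` at one or more later stages. This definition is used for
  analyses of allele-specific transcript level, avoiding the circularity of
  conditioning an allele-specific result on an allele-specific call.

Thresholds are applied as strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import AlleleFractions
from .types import ExpressionTable, SampleSheet, ValidationError

__all__ = ["ZygoticCalls", "call_allele_specific", "call_transcript_level",
           "first_zygotic_stage", "intersect_calls"]

DEFAULT_RPKM_MIN = 5.0
DEFAULT_PATERNAL_MIN_FRACTION = 0.40


@dataclass
class ZygoticCalls:
    """Zygotic classification result.

    For the allele_specific definition ``calls`` is a gene x stage boolean
    frame with NA where the gene is not callable at that stage; for the
    transcript_level definition it is a single-column frame (``zygotic``) of
    per-gene booleans.
    """

    definition: str
    calls: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def genes_at(self, stage: int) -> pd.Index:
        """Genes positively called zygotic at ``stage``."""
        if self.definition == "allele_specific":
            if stage not in self.calls.columns:
                return pd.Index([])
            col = self.calls[stage]
            return self.calls.index[col.fillna(False).astype(bool)]
        return self.calls.index[self.calls["zygotic"].astype(bool)]

    def stages(self) -> list[int]:
        if self.definition == "allele_specific":
            return [int(s) for s in self.calls.columns]
        return []


def call_allele_specific(expr: ExpressionTable, fractions: AlleleFractions,
                         sheet: SampleSheet,
                         rpkm_min: float = DEFAULT_RPKM_MIN,
                         paternal_min_fraction: float = DEFAULT_PATERNAL_MIN_FRACTION,
                         ) -> ZygoticCalls:
    """Stage-by-stage allele-specific zygotic calls (from female embryos)."""
    frac = fractions.frame
    stage_of = sheet.frame["stage"]
    calls = {}
    for stage in sheet.stages_present():
        females = sheet.samples(stage=stage, sex="female")
        if len(females) == 0:
            warnings.warn(f"no female samples at stage {stage}; stage skipped")
            continue
        mean_rpkm = expr.values[list(females)].mean(axis=1)
        mask = frac.index.get_level_values("sample_id").isin(set(females))
        genes = frac.index.get_level_values("gene_id")[mask]
        mean_p = frac.loc[mask, "p"].groupby(genes).mean()
        col = pd.Series(pd.NA, index=expr.values.index, dtype="boolean")
        callable_genes = mean_p.dropna().index
        col.loc[callable_genes] = (
            (mean_rpkm.reindex(callable_genes) > rpkm_min)
            & (mean_p.reindex(callable_genes) > paternal_min_fraction)
        ).to_numpy()
        calls[stage] = col
    return ZygoticCalls(
        definition="allele_specific",
        calls=pd.DataFrame(calls),
        thresholds={"rpkm_min": rpkm_min,
                    "paternal_min_fraction": paternal_min_fraction})


def call_transcript_level(expr: ExpressionTable, sheet: SampleSheet,
                          rpkm_min: float = DEFAULT_RPKM_MIN,
                          sustained: bool = False) -> ZygoticCalls:
    """Per-gene transcript-level zygotic calls.

    ``sustained=True`` additionally requires every stage after the first
    crossing to stay above ``rpkm_min`` (the strong reading of "subsequent
    stages"); the default accepts any single later stage.
    """
    stages = sheet.stages_present()
    if not stages:
        raise ValidationError("empty sample sheet")
    first = stages[0]
    stage_means = pd.DataFrame({
        s: expr.values[list(sheet.samples(stage=s))].mean(axis=1) for s in stages})
    no_deposit = stage_means[first] < rpkm_min
    later = stage_means[[s for s in stages if s != first]]
    if sustained:
        above = later.gt(rpkm_min)
        # all stages from the first crossing onward must stay above
        crossed = above.to_numpy()
        ok = np.zeros(len(later), dtype=bool)
        for i in range(len(later)):
            idx = np.flatnonzero(crossed[i])
            ok[i] = len(idx) > 0 and crossed[i, idx[0]:].all()
        expressed_later = pd.Series(ok, index=later.index)
    else:
        expressed_later = later.gt(rpkm_min).any(axis=1)
    calls = pd.DataFrame({"zygotic": (no_deposit & expressed_later)})
    return ZygoticCalls(definition="transcript_level", calls=calls,
                        thresholds={"rpkm_min": rpkm_min, "sustained": sustained})


def first_zygotic_stage(calls: ZygoticCalls) -> pd.Series:
    """Earliest stage at which each gene meets the stage-specific definition.

    Genes never called zygotic get NA.
    """
    if calls.definition != "allele_specific":
        raise ValueError("first_zygotic_stage requires allele_specific calls")
    frame = calls.calls
    out = pd.Series(pd.NA, index=frame.index, dtype="Int64")
    for stage in sorted(frame.columns):
        pos = frame[stage].fillna(False).astype(bool) & out.isna()
        out[pos] = int(stage)
    return out


def intersect_calls(calls_a: ZygoticCalls, calls_b: ZygoticCalls,
                    orthology: pd.DataFrame | None = None) -> ZygoticCalls:
    """Per-stage intersection of two call sets on a shared gene universe.

    ``orthology`` maps calls_a gene ids (first column) to calls_b ids (second
    column); identity mapping is assumed when omitted. Genes without a mapping
    are dropped (count logged via warning). The result is indexed by calls_a
    gene ids.
    """
    if calls_a.definition != calls_b.definition:
        raise ValueError("cannot intersect calls made under different definitions")
    if orthology is None:
        mapping = pd.Series(calls_a.calls.index, index=calls_a.calls.index)
    else:
        mapping = pd.Series(orthology.iloc[:, 1].to_numpy(),
                            index=orthology.iloc[:, 0].to_numpy())
    usable = calls_a.calls.index.intersection(mapping.index)
    mapped = mapping.reindex(usable)
    present = mapped.isin(calls_b.calls.index)
    dropped = len(calls_a.calls.index) - int(present.sum())
    if dropped:
        warnings.warn(f"{dropped} gene(s) without an orthology mapping dropped")
    usable = usable[present.to_numpy()]
    mapped = mapped.loc[usable]

    a = calls_a.calls.loc[usable]
    b = calls_b.calls.loc[mapped.to_numpy()]
    b.index = usable
    if calls_a.definition == "allele_specific":
        shared_stages = [s for s in a.columns if s in set(b.columns)]
        out = pd.DataFrame(index=usable)
        for s in shared_stages:
            out[s] = (a[s].fillna(False).astype(bool)
                      & b[s].fillna(False).astype(bool)).astype("boolean")
            if not out[s].any():
                warnings.warn(f"empty zygotic intersection at stage {s}")
    else:
        out = pd.DataFrame({"zygotic": a["zygotic"].astype(bool)
                            & b["zygotic"].astype(bool)})
    return ZygoticCalls(definition=calls_a.definition, calls=out,
                        thresholds=dict(calls_a.thresholds))
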