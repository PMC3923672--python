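"""Core data containers shared by every stage of the pipeline.

The analysis operates on four tables that mirror how a single-embryo
allele-specific RNA-seq experiment is organised:

* :class:`GeneAnnotation` — one row per gene: chromosome assignment, genomic
  interval (0-based half-open), neo-Y ORF status, and how many informative
  SNPs distinguish the parental lines within the gene.
* :class:`SampleSheet` — one row per embryo: species profile, ordinal
  developmental stage 1..8 (mapping to morphological stages 2 .. 12), sex and
  replicate number.
* :class:`ExpressionTable` — gene x sample RPKM matrix, with a flag recording
  whether per-sample autosomal normalization has been applied.
* :class:`AlleleCountTable` — per (gene, sample) maternal and paternal
  SNP-overlapping read tallies; for genes on the neo-sex chromosome in male
  embryos, additionally neo-X / neo-Y tallies from neo-divergence SNPs.

Missing allele rows mean "no SNP information", which is deliberately distinct
from observed zero counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Chromosome arms. Chromosome "3" is an ordinary autosome in the pse_like and
# mel_like karyotypes and the neo-XY pair in mir_like.
CHR2 = "2"
CHR4 = "4"
XL = "XL"
XR = "XR"
NEO = "3"
CHROMOSOMES: tuple[str, ...] = (CHR2, CHR4, XL, XR, NEO)
X_CHROMOSOMES = frozenset({XL, XR})
REFERENCE_AUTOSOMES = frozenset({CHR2, CHR4})

#: Ordinal stage -> morphological stage label (display metadata only).
STAGE_LABELS: dict[int, str] = {
    1: "2", 2: "4", 3: "mid-5", 4: "late-5", 5: "7", 6: "8/9", 7: "10", 8: "12",
}
STAGES: tuple[int, ...] = tuple(STAGE_LABELS)

SPECIES_PROFILES = ("pse_like", "mir_like", "mel_like")
SEXES = ("female", "male")
ORF_STATES = ("intact", "broken", "not_applicable")
STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a table violates one of the documented invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class GeneAnnotation:
    """Validated per-gene annotation.

    ``frame`` is indexed by ``gene_id`` with columns ``chromosome``, ``start``,
    ``end``, ``strand``, ``neoY_orf`` and ``n_informative_snps``.
    """

    frame: pd.DataFrame

    REQUIRED = ("chromosome", "start", "end", "strand", "neoY_orf", "n_informative_snps")

    def __post_init__(self) -> None:
        f = self.frame
        _require(f.index.is_unique, "duplicate gene_id in annotation")
        missing = [c for c in self.REQUIRED if c not in f.columns]
        _require(not missing, f"annotation missing columns: {missing}")
        _require(f["chromosome"].isin(CHROMOSOMES).all(),
                 "unknown chromosome in annotation")
        _require((f["start"] >= 0).all(), "negative start coordinate")
        bad = f.index[f["start"] >= f["end"]]
        _require(len(bad) == 0, f"start >= end for genes: {list(bad[:5])}")
        _require(f["strand"].isin(STRANDS).all(), "invalid strand value")
        _require(f["neoY_orf"].isin(ORF_STATES).all(), "invalid neoY_orf value")
        off_neo = f["chromosome"] != NEO
        _require((f.loc[off_neo, "neoY_orf"] == "not_applicable").all(),
                 "neoY_orf defined for a gene off the neo-XY chromosome")
        _require((f["n_informative_snps"] >= 0).all(),
                 "negative n_informative_snps")
        self.frame = f.copy()
        self.frame.index.name = "gene_id"

    @property
    def gene_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def chromosome(self) -> pd.Series:
        return self.frame["chromosome"]

    def genes_on(self, chromosomes) -> pd.Index:
        """Gene ids on the given chromosome(s)."""
        if isinstance(chromosomes, str):
            chromosomes = {chromosomes}
        return self.frame.index[self.frame["chromosome"].isin(set(chromosomes))]

    def snp_covered(self) -> pd.Index:
        return self.frame.index[self.frame["n_informative_snps"] > 0]


@dataclass
class SampleSheet:
    """Embryo-level metadata, indexed by ``sample_id``."""

    frame: pd.DataFrame

    REQUIRED = ("species", "stage", "sex", "replicate")

    def __post_init__(self) -> None:
        f = self.frame
        _require(f.index.is_unique, "duplicate sample_id in sample sheet")
        missing = [c for c in self.REQUIRED if c not in f.columns]
        _require(not missing, f"sample sheet missing columns: {missing}")
        _require(f["species"].isin(SPECIES_PROFILES).all(), "unknown species profile")
        _require(f["stage"].isin(STAGES).all(), "stage outside 1..8")
        _require(f["sex"].isin(SEXES + ("unknown",)).all(), "invalid sex")
        _require((f["replicate"] >= 1).all(), "replicate must be >= 1")
        dup = f.duplicated(subset=["species", "stage", "sex", "replicate"])
        _require(not dup.any(), "duplicate (species, stage, sex, replicate)")
        self.frame = f.copy()
        self.frame.index.name = "sample_id"

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index

    def samples(self, stage=None, sex=None, species=None) -> pd.Index:
        """Sample ids matching the given stage / sex / species filters."""
        mask = pd.Series(True, index=self.frame.index)
        if stage is not None:
            mask &= self.frame["stage"] == stage
        if sex is not None:
            mask &= self.frame["sex"] == sex
        if species is not None:
            mask &= self.frame["species"] == species
        return self.frame.index[mask]

    def stages_present(self) -> list[int]:
        return sorted(self.frame["stage"].unique())


@dataclass
class ExpressionTable:
    """Gene x sample RPKM matrix.

    ``normalized`` records whether :func:`embryocomp.preprocess.normalize_autosomal`
    has been applied; ``scale_factors`` then holds the per-sample factor used, so
    downstream allele-level analyses can put read counts on the same scale.
    """

    values: pd.DataFrame
    normalized: bool = False
    normalization_reference: float | None = None
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values
        _require(v.index.is_unique, "duplicate gene_id in expression table")
        _require(v.columns.is_unique, "duplicate sample_id in expression table")
        arr = v.to_numpy(dtype=float)
        _require(np.isfinite(arr).all(), "non-finite expression value")
        _require((arr >= 0).all(), "negative expression value")
        self.values = v.astype(float)
        self.values.index.name = "gene_id"
        self.values.columns.name = "sample_id"


@dataclass
class AlleleCountTable:
    """Per (gene, sample) maternal/paternal SNP-read tallies.

    ``frame`` has a (gene_id, sample_id) MultiIndex and columns
    ``maternal_reads``, ``paternal_reads``, ``n_snps_observed`` plus optional
    ``neoX_reads`` / ``neoY_reads`` (NaN where no neo-divergence SNPs exist).
    Genes without informative SNPs simply have no rows.
    """

    frame: pd.DataFrame

    REQUIRED = ("maternal_reads", "paternal_reads", "n_snps_observed")

    def __post_init__(self) -> None:
        f = self.frame
        _require(isinstance(f.index, pd.MultiIndex) and f.index.nlevels == 2,
                 "allele table must be indexed by (gene_id, sample_id)")
        _require(f.index.is_unique, "duplicate (gene, sample) in allele table")
        missing = [c for c in self.REQUIRED if c not in f.columns]
        _require(not missing, f"allele table missing columns: {missing}")
        for c in self.REQUIRED:
            _require((f[c] >= 0).all(), f"negative {c} in allele table")
        for c in ("neoX_reads", "neoY_reads"):
            if c in f.columns:
                vals = f[c].dropna()
                _require((vals >= 0).all(), f"negative {c} in allele table")
        self.frame = f.copy()
        self.frame.index.names = ["gene_id", "sample_id"]

    @property
    def has_neo_columns(self) -> bool:
        return {"neoX_reads", "neoY_reads"} <= set(self.frame.columns)

    def total_reads(self) -> pd.Series:
        return self.frame["maternal_reads"] + self.frame["paternal_reads"]


@dataclass
class BootstrapResult:
    """Point estimate with an empirical 95% bootstrap confidence interval.

    The interval is the 2.5% and 97.5% quantiles of the statistic over
    ``n_boot`` gene-resampling replicates.
    """

    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        # quantile granularity at tiny n can put the point estimate a hair
        # outside; allow a small slack
        span = max(abs(self.point_estimate), 1.0)
        _require(self.ci_low <= self.point_estimate + 1e-9 * span,
                 "ci_low above point estimate")
        _require(self.ci_high >= self.point_estimate - 1e-9 * span,
                 "ci_high below point estimate")

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high
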