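"""Synthetic single-embryo experiment generator with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
timecourse of eight morphologically staged timepoints, three female and three
male embryos per stage, with per-gene transcript levels composed of

* a **maternal** component, deposited equally in both sexes and carrying only
  maternal alleles, decaying geometrically per stage after the
  maternal-to-zygotic transition (MZT); and
* a **zygotic** component that switches on at a per-gene onset stage, scales
  with chromosome copy number, and — on X chromosomes in males — is multiplied
  by a per-stage compensation factor in [1, 2] describing upregulation of the
  single male X.

Allele-specific read counts are drawn by splitting each gene's
SNP-overlapping reads between the maternal and paternal allele according to
the composition of its transcript pool: zygotic autosomal transcripts are
biallelically balanced, maternal transcripts are all-maternal, and the male X
is all-maternal. On the neo-XY pair (mir_like profile) male reads split
between the maternal neo-X and the paternal neo-Y according to the gene's
neo-Y retention level.

Three karyotype profiles are provided: ``mel_like`` (single ancestral X,
chromosome 3 autosomal, early partial compensation), ``pse_like`` (XL + XR),
and ``mir_like`` (XL + XR + neo-XY, zygotic activation and compensation each
delayed one stage).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    CHR2,
    CHR4,
    CHROMOSOMES,
    NEO,
    STAGES,
    X_CHROMOSOMES,
    XL,
    XR,
    AlleleCountTable,
    ExpressionTable,
    GeneAnnotation,
    SampleSheet,
)

__all__ = ["SimulationConfig", "SimulationTruth", "default_config", "simulate_experiment"]


@dataclass
class SimulationConfig:
    """All knobs of the generative model. See module docstring for the model."""

    profile: str
    #: genes simulated on each chromosome arm
    n_genes_per_chromosome: dict[str, int]
    #: embryos per (stage, sex)
    n_replicates: int = 3
    #: probability a gene carries maternally deposited transcript
    maternal_fraction: float = 0.6
    #: probability a gene is zygotically transcribed
    zygotic_fraction: float = 0.5
    #: log-normal deposition level: median RPKM and log-scale sd
    maternal_mean: float = 20.0
    maternal_dispersion: float = 0.8
    #: fraction of remaining maternal transcript degraded per stage after MZT
    maternal_decay_per_stage: float = 0.35
    #: ordinal stage of widespread zygotic genome activation
    mzt_stage: int = 3
    #: P(zygotic gene first activates at stage s); keys are ordinal stages
    zygotic_onset_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.05, 3: 0.55, 4: 0.20, 5: 0.10, 6: 0.10})
    #: log-normal per-copy zygotic rate: median RPKM and log-scale sd.
    #: The median sits well above the 5 RPKM analysis floor so that the
    #: inclusion rule does not differentially truncate hemizygous male
    #: levels, matching the regime in which the sex-ratio analyses operate.
    zygotic_rate_mean: float = 25.0
    zygotic_rate_dispersion: float = 0.8
    #: stage -> male-X per-copy upregulation factor in [1, 2], non-decreasing
    compensation_trajectory: dict[int, float] = field(
        default_factory=lambda: {s: 1.0 for s in STAGES})
    #: separate trajectory for the neo-X (defaults to compensation_trajectory)
    neo_compensation_trajectory: dict[int, float] | None = None
    #: if set, each zygotic X gene is individually "compensated" with this
    #: probability (compensated genes follow the trajectory, the rest stay at 1)
    per_gene_compensated_fraction: float | None = None
    #: stages by which zygotic activation lags the pse_like reference
    species_delay_stages: int = 0
    # --- neo-XY (mir_like only) ---
    neoY_broken_fraction: float = 0.5
    neoY_silenced_fraction: float = 0.3
    neoY_retention_beta: tuple[float, float] = (2.0, 2.0)
    #: fraction of expressed genes with parental-line SNPs, per chromosome
    snp_informative_fraction: dict[str, float] = field(
        default_factory=lambda: {c: 0.9 for c in CHROMOSOMES})
    #: fraction of neo-XY genes with neo-divergence SNPs
    neo_snp_fraction: float = 0.68
    #: mean informative SNPs per covered gene (shifted Poisson)
    snps_per_gene_mean: float = 5.0
    #: expected SNP-overlapping reads for a gene at maternal_mean RPKM
    read_depth: float = 200.0
    #: count noise: "poisson" or "negative_binomial" (gamma-Poisson, given size)
    noise_model: str = "negative_binomial"
    nb_size: float = 20.0
    #: RPKM is derived from simulated counts at this many reads per RPKM unit
    rpkm_reads_per_unit: float = 10.0
    gene_length_bp: int = 1000
    #: log-normal coefficient of variation of per-embryo sequencing depth
    depth_cv: float = 0.0
    #: paternal share of zygotic transcript from a biallelic pair (allelic
    #: imbalance knob; 0.5 = balanced, the assumption behind doubling p)
    zygotic_paternal_share: float = 0.5
    #: place zygotic genes in clusters along the chromosome
    zygotic_clustering: bool = False
    cluster_sd_bp: float = 50_000.0
    chromosome_length_bp: dict[str, float] = field(
        default_factory=lambda: {CHR2: 30e6, CHR4: 25e6, XL: 20e6, XR: 30e6, NEO: 25e6})
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_genes_per_chromosome) - set(CHROMOSOMES)
        if unknown:
            raise ValueError(f"unknown chromosome keys in config: {sorted(unknown)}")
        probs = list(self.zygotic_onset_distribution.values())
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValueError("zygotic_onset_distribution must be a probability map summing to 1")
        traj = [self.compensation_trajectory.get(s, 1.0) for s in STAGES]
        if any(b < a - 1e-12 for a, b in zip(traj, traj[1:])):
            raise ValueError("compensation_trajectory must be non-decreasing in stage")
        if any(f < 1.0 - 1e-12 or f > 2.0 + 1e-12 for f in traj):
            raise ValueError("compensation factors must lie in [1, 2]")

    def male_x_factor(self, stage: int, neo: bool = False) -> float:
        """Per-copy male-X factor at ``stage``, shifted by the species delay."""
        traj = self.compensation_trajectory
        if neo and self.neo_compensation_trajectory is not None:
            traj = self.neo_compensation_trajectory
        return traj.get(stage - self.species_delay_stages, 1.0)


@dataclass
class SimulationTruth:
    """Ground-truth generative parameters, the oracle for recovery tests.

    ``genes`` is indexed by gene_id with the per-gene parameters
    (``is_zygotic``, ``onset_stage``, ``maternal_level``, ``zygotic_level``
    per copy, ``compensated``, ``neoY_orf``, ``neoY_retention``); ``samples``
    records each embryo's true stage and sex; ``config`` is the generating
    configuration.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    config: SimulationConfig

    def expected_levels(self, stage: int, sex: str) -> pd.DataFrame:
        """Noise-free expected transcript levels per gene at (stage, sex).

        Columns: ``maternal`` (deposited), ``zygotic`` (total across copies),
        ``total``, ``paternal_allele`` (share of total carrying the paternal
        allele) and, on the neo-XY in males, ``neoY`` (share from the neo-Y).
        """
        cfg = self.config
        g = self.genes
        decay = (1 - cfg.maternal_decay_per_stage) ** max(0, stage - cfg.mzt_stage)
        maternal = g["maternal_level"].to_numpy() * decay
        active = (g["is_zygotic"] & (g["onset_stage"] <= stage)).to_numpy()
        z = np.where(active, g["zygotic_level"].to_numpy(), 0.0)
        chrom = g["chromosome"].to_numpy()
        neo_is_sex = cfg.profile == "mir_like"
        on_x = np.isin(chrom, list(X_CHROMOSOMES))
        on_neo = chrom == NEO

        factor = np.where(g["compensated"].to_numpy(),
                          cfg.male_x_factor(stage), 1.0)
        neo_factor = np.where(g["compensated"].to_numpy(),
                              cfg.male_x_factor(stage, neo=True), 1.0)
        share = cfg.zygotic_paternal_share

        zygotic = np.where(on_x | (on_neo & neo_is_sex), 0.0, 2 * z)
        paternal = np.where(on_x | (on_neo & neo_is_sex), 0.0, 2 * z * share)
        neoY = np.zeros_like(z)
        if sex == "female":
            sexed = 2 * z
            zygotic = np.where(on_x | (on_neo & neo_is_sex), sexed, zygotic)
            paternal = np.where(on_x | (on_neo & neo_is_sex), sexed * share, paternal)
        else:
            zygotic = np.where(on_x, z * factor, zygotic)
            if neo_is_sex:
                retention = g["neoY_retention"].to_numpy()
                neoY = np.where(on_neo, z * retention, 0.0)
                zygotic = np.where(on_neo, z * neo_factor + neoY, zygotic)
                paternal = np.where(on_neo, neoY, paternal)
        total = maternal + zygotic
        return pd.DataFrame({
            "maternal": maternal, "zygotic": zygotic, "total": total,
            "paternal_allele": paternal, "neoY": neoY,
        }, index=g.index)


_PROFILE_GENES = {
    "mel_like": {CHR2: 500, CHR4: 100, XL: 400, NEO: 400},
    "pse_like": {CHR2: 500, CHR4: 100, XL: 300, XR: 500, NEO: 400},
    "mir_like": {CHR2: 500, CHR4: 100, XL: 300, XR: 500, NEO: 400},
}

# Compensation onset mirrors the study design: the male X rises above the
# female per-copy level from ordinal stage 5 (morphological stage 7) in the
# pse_like profile, one stage later in mir_like, reaching full two-fold
# upregulation by the final stage.
_PSE_TRAJECTORY = {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 4 / 3, 6: 5 / 3, 7: 2.0, 8: 2.0}


def default_config(profile: str, seed: int = 0) -> SimulationConfig:
    """Documented default configuration for one of the three karyotype profiles.

    ``mel_like``: one ancestral X, chromosome 3 autosomal; half of zygotic X
    genes are fully compensated (factor 2) from activation onward, the rest
    uncompensated — the early-embryonic partial compensation regime.
    ``pse_like``: XL + XR, no early compensation, MSL-like ramp from stage 5.
    ``mir_like``: additionally the neo-XY pair; zygotic activation and the
    compensation ramp are each delayed by one stage.
    """
    if profile not in _PROFILE_GENES:
        raise ValueError(f"unknown profile: {profile!r}")
    n_genes = dict(_PROFILE_GENES[profile])
    kwargs: dict = {}
    if profile == "mel_like":
        kwargs.update(
            compensation_trajectory={s: 2.0 for s in STAGES},
            per_gene_compensated_fraction=0.5,
            snp_informative_fraction={c: 0.92 for c in CHROMOSOMES},
        )
    elif profile == "pse_like":
        kwargs.update(
            compensation_trajectory=dict(_PSE_TRAJECTORY),
            snp_informative_fraction={c: 0.92 for c in CHROMOSOMES},
        )
    else:  # mir_like: the pse_like ramp plus a one-stage species delay, which
        # simulate_experiment applies to both zygotic onset and compensation
        kwargs.update(
            compensation_trajectory=dict(_PSE_TRAJECTORY),
            species_delay_stages=1,
            snp_informative_fraction={c: 0.75 for c in CHROMOSOMES},
        )
    return SimulationConfig(profile=profile, n_genes_per_chromosome=n_genes,
                            seed=seed, **kwargs)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 cfg: SimulationConfig) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if cfg.noise_model == "poisson":
        return rng.poisson(mean)
    if cfg.noise_model == "negative_binomial":
        lam = rng.gamma(cfg.nb_size, np.maximum(mean, 1e-12) / cfg.nb_size)
        return rng.poisson(np.where(mean > 0, lam, 0.0))
    raise ValueError(f"unknown noise model: {cfg.noise_model}")


def _draw_genes(rng: np.random.Generator, cfg: SimulationConfig) -> pd.DataFrame:
    records = []
    neo_is_sex = cfg.profile == "mir_like"
    onset_stages = np.array(list(cfg.zygotic_onset_distribution), dtype=int)
    onset_probs = np.array(list(cfg.zygotic_onset_distribution.values()))
    for chrom, n in sorted(cfg.n_genes_per_chromosome.items()):
        if n == 0:
            continue
        L = cfg.chromosome_length_bp[chrom]
        is_zyg = rng.random(n) < cfg.zygotic_fraction
        has_mat = rng.random(n) < cfg.maternal_fraction
        # a gene expressed neither maternally nor zygotically is simply silent
        m_level = np.where(
            has_mat,
            cfg.maternal_mean * rng.lognormal(0.0, cfg.maternal_dispersion, n),
            0.0)
        z_level = np.where(
            is_zyg,
            cfg.zygotic_rate_mean * rng.lognormal(0.0, cfg.zygotic_rate_dispersion, n),
            0.0)
        onset = np.where(is_zyg, rng.choice(onset_stages, size=n, p=onset_probs), 0)
        onset = np.where(is_zyg, np.minimum(8, onset + cfg.species_delay_stages), 0)
        if cfg.per_gene_compensated_fraction is None:
            compensated = np.ones(n, dtype=bool)
        else:
            # exactly this fraction of zygotic genes, not a Bernoulli draw:
            # the mixture composition is part of the design, not noise
            compensated = np.ones(n, dtype=bool)
            zyg_idx = np.flatnonzero(is_zyg)
            k = int(round(cfg.per_gene_compensated_fraction * len(zyg_idx)))
            chosen = rng.permutation(zyg_idx)[:k]
            compensated[zyg_idx] = False
            compensated[chosen] = True
        snp_frac = cfg.snp_informative_fraction.get(chrom, 0.9)
        has_snps = rng.random(n) < snp_frac
        n_snps = np.where(has_snps, 1 + rng.poisson(cfg.snps_per_gene_mean - 1, n), 0)
        if neo_is_sex and chrom == NEO:
            orf = np.where(rng.random(n) < cfg.neoY_broken_fraction, "broken", "intact")
            a, b = cfg.neoY_retention_beta
            retention = np.where(rng.random(n) < cfg.neoY_silenced_fraction,
                                 0.0, rng.beta(a, b, n))
            has_neo_snps = rng.random(n) < cfg.neo_snp_fraction
        else:
            orf = np.full(n, "not_applicable")
            retention = np.zeros(n)
            has_neo_snps = np.zeros(n, dtype=bool)
        start = np.sort(rng.uniform(0, L - 2 * cfg.gene_length_bp, n)).astype(int)
        if cfg.zygotic_clustering and is_zyg.sum() >= 2:
            n_centers = max(1, int(is_zyg.sum()) // 10)
            centers = rng.uniform(0, L, n_centers)
            pos = rng.normal(centers[rng.integers(0, n_centers, int(is_zyg.sum()))],
                             cfg.cluster_sd_bp)
            start[is_zyg] = np.clip(pos, 0, L - 2 * cfg.gene_length_bp).astype(int)
        for i in range(n):
            records.append({
                "gene_id": f"{chrom}_g{i:04d}",
                "chromosome": chrom,
                "start": int(start[i]),
                "end": int(start[i]) + cfg.gene_length_bp,
                "strand": "+" if rng.random() < 0.5 else "-",
                "is_zygotic": bool(is_zyg[i]),
                "onset_stage": int(onset[i]) if is_zyg[i] else 0,
                "maternal_level": float(m_level[i]),
                "zygotic_level": float(z_level[i]),
                "compensated": bool(compensated[i]),
                "neoY_orf": str(orf[i]),
                "neoY_retention": float(retention[i]),
                "n_informative_snps": int(n_snps[i]),
                "has_neo_snps": bool(has_neo_snps[i]),
            })
    return pd.DataFrame(records).set_index("gene_id")


def simulate_experiment(config: SimulationConfig,
                        gene_params: pd.DataFrame | None = None,
                        ) -> tuple[ExpressionTable, AlleleCountTable, SampleSheet,
                                   GeneAnnotation, SimulationTruth]:
    """Generate a full synthetic experiment.

    Returns the expression table (RPKM derived from simulated counts at fixed
    gene length), the allele-count table (SNP-covered genes only), the sample
    sheet, the gene annotation, and the ground truth. Bit-identical for a
    given config (including seed).

    ``gene_params`` reuses the per-gene parameter table (``truth.genes``) of
    an earlier simulation instead of drawing a fresh one — the way to emulate
    a second species whose orthologous genes share the same expression
    program while its embryos are sequenced independently.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _draw_genes(rng, cfg) if gene_params is None else gene_params.copy()

    # sample sheet: n_replicates embryos per stage per sex
    rows = []
    for stage in STAGES:
        for sex in ("female", "male"):
            for rep in range(1, cfg.n_replicates + 1):
                rows.append({
                    "sample_id": f"{cfg.profile[:3]}_s{stage}_{sex[0]}{rep}",
                    "species": cfg.profile, "stage": stage, "sex": sex,
                    "replicate": rep,
                })
    sheet_frame = pd.DataFrame(rows).set_index("sample_id")
    sheet = SampleSheet(sheet_frame)

    truth = SimulationTruth(genes=genes, samples=sheet_frame.copy(), config=cfg)

    neo_is_sex = cfg.profile == "mir_like"
    snp_genes = genes.index[genes["n_informative_snps"] > 0]
    n_snps = genes.loc[snp_genes, "n_informative_snps"].to_numpy()
    neo_snp_mask = (genes["has_neo_snps"] & (genes["chromosome"] == NEO)).to_numpy()

    expr_cols: dict[str, np.ndarray] = {}
    allele_frames: list[pd.DataFrame] = []
    level_cache: dict[tuple[int, str], pd.DataFrame] = {}

    for sid, row in sheet_frame.iterrows():
        stage, sex = int(row["stage"]), row["sex"]
        key = (stage, sex)
        if key not in level_cache:
            level_cache[key] = truth.expected_levels(stage, sex)
        lv = level_cache[key]
        depth_factor = (rng.lognormal(0.0, cfg.depth_cv)
                        if cfg.depth_cv > 0 else 1.0)

        # expression: counts at fixed gene length -> RPKM
        counts = _draw_counts(rng, lv["total"].to_numpy() * cfg.rpkm_reads_per_unit, cfg)
        expr_cols[sid] = counts / cfg.rpkm_reads_per_unit

        # allele counts at SNP-covered genes
        sub = lv.loc[snp_genes]
        mean_reads = (cfg.read_depth / cfg.maternal_mean
                      * sub["total"].to_numpy() * depth_factor)
        total = _draw_counts(rng, mean_reads, cfg)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_pat = np.where(sub["total"] > 0,
                             sub["paternal_allele"] / sub["total"], 0.0)
        paternal = rng.binomial(total, np.clip(p_pat, 0, 1))
        maternal = total - paternal
        observed = np.minimum(n_snps, total)
        frame = pd.DataFrame({
            "maternal_reads": maternal.astype(float),
            "paternal_reads": paternal.astype(float),
            "n_snps_observed": observed.astype(int),
        }, index=snp_genes)
        if neo_is_sex:
            frame["neoX_reads"] = np.nan
            frame["neoY_reads"] = np.nan
            if sex == "male":
                neo_ids = genes.index[neo_snp_mask].intersection(snp_genes)
                nlv = lv.loc[neo_ids]
                n_total = _draw_counts(
                    rng, (cfg.read_depth / cfg.maternal_mean
                          * nlv["total"].to_numpy() * depth_factor), cfg)
                with np.errstate(invalid="ignore", divide="ignore"):
                    p_neoY = np.where(nlv["total"] > 0,
                                      nlv["neoY"] / nlv["total"], 0.0)
                neoY = rng.binomial(n_total, np.clip(p_neoY, 0, 1))
                frame.loc[neo_ids, "neoY_reads"] = neoY.astype(float)
                frame.loc[neo_ids, "neoX_reads"] = (n_total - neoY).astype(float)
        frame.index.name = "gene_id"
        frame["sample_id"] = sid
        allele_frames.append(frame.reset_index())

    values = pd.DataFrame(expr_cols, index=genes.index)
    expr = ExpressionTable(values)

    allele_frame = pd.concat(allele_frames, ignore_index=True)
    allele = AlleleCountTable(allele_frame.set_index(["gene_id", "sample_id"]))

    ann = GeneAnnotation(genes[["chromosome", "start", "end", "strand",
                                "neoY_orf", "n_informative_snps"]])
    return expr, allele, sheet, ann, truth


def config_with(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Return a copy of ``config`` with fields replaced (deep-copies maps)."""
    return replace(copy.deepcopy(config), **overrides)
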