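"""Readers, writers and cross-table validation.

Formats are deliberately plain text: BED6+2 or GFF3 for the gene annotation,
tab-separated tables (header row, UTF-8, '.' decimal) for expression, allele
counts and the sample sheet. Coordinates are held 0-based half-open internally
(BED convention); GFF3 input is converted on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    NEO,
    X_CHROMOSOMES,
    AlleleCountTable,
    ExpressionTable,
    GeneAnnotation,
    SampleSheet,
    ValidationError,
)

_FLOAT_FMT = "%.6g"  # declared round-trip precision: 6 significant digits


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


# ---------------------------------------------------------------------------
# annotation

_BED_COLS = ["chromosome", "start", "end", "gene_id", "score", "strand",
             "neoY_orf", "n_informative_snps"]


def read_annotation(path: str | Path, format: str | None = None) -> GeneAnnotation:
    """Read a gene annotation from BED6+2 or GFF3.

    BED carries ``neoY_orf`` and ``n_informative_snps`` as extra columns 7-8;
    GFF3 carries them as ``neoY_orf=`` and ``informative_snps=`` attributes.
    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "GFF" if path.suffix.lower() in {".gff", ".gff3"} else "BED"
    format = format.upper()
    if format == "BED":
        rows = _read_bed(path)
    elif format == "GFF":
        rows = _read_gff(path)
    else:
        raise ValueError(f"unknown annotation format: {format}")
    frame = pd.DataFrame(rows).set_index("gene_id")
    frame["start"] = frame["start"].astype(int)
    frame["end"] = frame["end"].astype(int)
    frame["n_informative_snps"] = frame["n_informative_snps"].astype(int)
    return GeneAnnotation(frame[["chromosome", "start", "end", "strand",
                                 "neoY_orf", "n_informative_snps"]])


def _read_bed(path: Path) -> list[dict]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns")
            try:
                rows.append({
                    "chromosome": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "gene_id": parts[3],
                    "strand": parts[5],
                    "neoY_orf": parts[6] if len(parts) > 6 else "not_applicable",
                    "n_informative_snps": int(parts[7]) if len(parts) > 7 else 0,
                })
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def _read_gff(path: Path) -> list[dict]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            attrs = {}
            for item in parts[8].split(";"):
                item = item.strip()
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            if "ID" not in attrs:
                raise ParseError(f"{path}:{lineno}: missing ID attribute")
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start")
            rows.append({
                "chromosome": parts[0],
                "start": start1 - 1,  # GFF is 1-based inclusive
                "end": end1,
                "gene_id": attrs["ID"],
                "strand": parts[6],
                "neoY_orf": attrs.get("neoY_orf", "not_applicable"),
                "n_informative_snps": int(attrs.get("informative_snps", 0)),
            })
    return rows


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    """Write annotation as BED6+2 (score column fixed at 0)."""
    f = ann.frame
    out = pd.DataFrame({
        "chromosome": f["chromosome"],
        "start": f["start"],
        "end": f["end"],
        "gene_id": f.index,
        "score": 0,
        "strand": f["strand"],
        "neoY_orf": f["neoY_orf"],
        "n_informative_snps": f["n_informative_snps"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# tabular data

def read_expression(path: str | Path) -> ExpressionTable:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(values)


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", index_col=0,
                        dtype={"stage": int, "replicate": int})
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t")


def read_allele_counts(path: str | Path) -> AlleleCountTable:
    frame = pd.read_csv(path, sep="\t", index_col=[0, 1])
    return AlleleCountTable(frame)


def write_allele_counts(allele: AlleleCountTable, path: str | Path) -> None:
    allele.frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_tables(expr_path, allele_path, sheet_path, ann: GeneAnnotation | None = None,
                ) -> tuple[ExpressionTable, AlleleCountTable, SampleSheet]:
    """Read and cross-validate the expression / allele / sample-sheet triple.

    Genes present in the expression table but absent from the allele table are
    allowed (they lack informative SNPs) and stay absent rather than being
    zero-filled. When an annotation is supplied the male-X rule is enforced:
    X-linked genes in male embryos must have zero paternal reads.
    """
    expr = read_expression(expr_path)
    allele = read_allele_counts(allele_path)
    sheet = read_sample_sheet(sheet_path)
    validate_tables(expr, allele, sheet, ann)
    return expr, allele, sheet


def validate_tables(expr: ExpressionTable, allele: AlleleCountTable,
                    sheet: SampleSheet, ann: GeneAnnotation | None = None) -> None:
    """Cross-table consistency checks; raises ValidationError on failure."""
    extra = set(expr.values.columns) - set(sheet.sample_ids)
    if extra:
        raise ValidationError(f"expression samples absent from sample sheet: {sorted(extra)[:5]}")
    extra = set(allele.frame.index.get_level_values("sample_id")) - set(sheet.sample_ids)
    if extra:
        raise ValidationError(f"allele-table samples absent from sample sheet: {sorted(extra)[:5]}")
    if ann is not None:
        unknown = set(expr.values.index) - set(ann.gene_ids)
        if unknown:
            raise ValidationError(f"expression genes absent from annotation: {sorted(unknown)[:5]}")
        _check_male_x(allele, sheet, ann)


def _check_male_x(allele: AlleleCountTable, sheet: SampleSheet,
                  ann: GeneAnnotation) -> None:
    males = set(sheet.samples(sex="male"))
    x_genes = set(ann.genes_on(X_CHROMOSOMES))
    f = allele.frame
    idx = f.index
    mask = (idx.get_level_values("gene_id").isin(x_genes)
            & idx.get_level_values("sample_id").isin(males))
    bad = f.loc[mask & (f["paternal_reads"] > 0).to_numpy()] if mask.any() else f.iloc[:0]
    if len(bad):
        g, s = bad.index[0]
        raise ValidationError(
            f"male sample {s} has paternal reads for X-linked gene {g} "
            "(males have no paternal X)")


def genes_without_allele_data(expr: ExpressionTable, allele: AlleleCountTable) -> pd.Index:
    """Expression genes with no allele information at all."""
    covered = set(allele.frame.index.get_level_values("gene_id"))
    return expr.values.index[~expr.values.index.isin(covered)]


# ---------------------------------------------------------------------------
# sex verification

def verify_sex(expr: ExpressionTable, allele: AlleleCountTable, ann: GeneAnnotation,
               sheet: SampleSheet | None = None, *, male_max_fraction: float = 0.02,
               female_band: tuple[float, float] = (0.3, 0.7),
               min_zygotic_fraction: float = 0.10,
               min_reads: float = 50.0) -> pd.DataFrame:
    """Call each embryo's sex from the allele-specific data.

    The total paternal read fraction over X-linked (XL/XR) genes is near zero
    in males (males carry no paternal X) and near the autosomal paternal
    fraction in females. Before the zygotic genome activates, every read is
    maternal in both sexes, so a call is only attempted when the autosomal
    paternal fraction shows zygotic transcription (>= ``min_zygotic_fraction``).

    Returns a frame indexed by sample_id with columns ``x_paternal_fraction``,
    ``autosomal_paternal_fraction``, ``called_sex`` and, when a sheet is given,
    ``sheet_sex`` and ``agrees``. Disagreements are reported, never silently
    overwritten.
    """
    f = allele.frame
    gene_chrom = ann.chromosome
    chroms = gene_chrom.reindex(f.index.get_level_values("gene_id")).to_numpy()
    samples = f.index.get_level_values("sample_id")

    def _fraction(mask: np.ndarray) -> pd.DataFrame:
        sub = f[mask].groupby(samples[mask])[["maternal_reads", "paternal_reads"]].sum()
        tot = sub["maternal_reads"] + sub["paternal_reads"]
        return pd.DataFrame({"fraction": sub["paternal_reads"] / tot, "reads": tot})

    on_x = np.isin(chroms, list(X_CHROMOSOMES))
    on_auto = ~on_x & (chroms != NEO)
    x_frac = _fraction(on_x)
    a_frac = _fraction(on_auto)

    all_samples = sheet.sample_ids if sheet is not None else pd.Index(sorted(set(samples)))
    out = pd.DataFrame(index=all_samples)
    out.index.name = "sample_id"
    out["x_paternal_fraction"] = x_frac["fraction"].reindex(all_samples)
    out["autosomal_paternal_fraction"] = a_frac["fraction"].reindex(all_samples)
    x_reads = x_frac["reads"].reindex(all_samples).fillna(0)

    calls = []
    for sid in all_samples:
        xf = out.at[sid, "x_paternal_fraction"]
        af = out.at[sid, "autosomal_paternal_fraction"]
        if (np.isnan(xf) or np.isnan(af) or x_reads[sid] < min_reads
                or af < min_zygotic_fraction):
            calls.append("unknown")
            if np.isnan(xf):
                warnings.warn(f"sample {sid}: no informative X-linked genes; sex unknown")
        elif xf < male_max_fraction:
            calls.append("male")
        elif female_band[0] <= xf <= female_band[1]:
            calls.append("female")
        else:
            calls.append("unknown")
    out["called_sex"] = calls

    if sheet is not None:
        out["sheet_sex"] = sheet.frame["sex"].reindex(all_samples)
        out["agrees"] = (out["called_sex"] == out["sheet_sex"]) | (out["called_sex"] == "unknown")
        n_bad = int((~out["agrees"]).sum())
        if n_bad:
            warnings.warn(f"{n_bad} sample(s) disagree with the sample sheet sex")
    return out
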