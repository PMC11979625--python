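"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-delimited with "NA" as the missing-value token.
Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted at the boundary. Floats are written with 10 significant digits
so a write/read round trip reproduces in-memory content.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GwasSummary,
    LdReference,
    VariantPanel,
    two_sided_p,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"
_NA = "NA"


def _to_tsv(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep=_NA)


# ---------------------------------------------------------------------------
# GWAS summary statistics

_GWAS_WRITE_COLS = {"snp": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1",
                    "a2": "A2", "z": "Z", "p": "P", "n": "N"}


def write_gwas(gwas: GwasSummary, path: Path | str) -> None:
    out = gwas.table.rename(columns=_GWAS_WRITE_COLS)
    _to_tsv(out[[c for c in _GWAS_WRITE_COLS.values() if c in out.columns]], path)


def read_gwas(path: Path | str) -> GwasSummary:
    """Load a GWAS summary TSV (SNP, CHR, BP, A1, A2, and Z or BETA/SE).

    z is derived as BETA/SE when Z is absent; P is recomputed from z when
    absent or inconsistent beyond 1e-6 relative (the number of corrections is
    logged). Errors name 1-based data line numbers (line 1 is the header).
    """
    df = pd.read_csv(path, sep="\t", na_values=[_NA])
    required = ["SNP", "CHR", "BP", "A1", "A2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "Z" not in df.columns and not {"BETA", "SE"}.issubset(df.columns):
        raise ValueError(f"{path}: needs either a Z column or BETA and SE")

    def lines(mask) -> list[int]:
        return (np.flatnonzero(np.asarray(mask)) + 2).tolist()

    dup = df["SNP"].duplicated(keep=False)
    if dup.any():
        ids = sorted(df.loc[dup, "SNP"].unique().tolist())
        raise ValueError(f"{path}: duplicated SNP ids {ids} at lines {lines(dup)}")

    if "Z" in df.columns:
        z = pd.to_numeric(df["Z"], errors="coerce")
    else:
        beta = pd.to_numeric(df["BETA"], errors="coerce")
        se = pd.to_numeric(df["SE"], errors="coerce")
        z = beta / se
    bad = ~np.isfinite(z.to_numpy(float))
    if bad.any():
        raise ValueError(f"{path}: non-numeric or undefined z at lines {lines(bad)}")
    z = z.to_numpy(float)

    p_expected = two_sided_p(z)
    if "P" in df.columns:
        p = pd.to_numeric(df["P"], errors="coerce").to_numpy(float)
        known = ~np.isnan(p)
        invalid = known & ((p <= 0) | (p > 1))
        if invalid.any():
            raise ValueError(f"{path}: P outside (0, 1] at lines {lines(invalid)}")
        inconsistent = known & (np.abs(p - p_expected) / p_expected > 1e-6)
        n_fix = int(inconsistent.sum() + (~known).sum())
    else:
        n_fix = len(df)
    if n_fix:
        logger.info("%s: recomputed %d p-values from z", path, n_fix)

    table = pd.DataFrame(
        {
            "snp": df["SNP"].astype(str),
            "chrom": df["CHR"],
            "pos": df["BP"].astype(int),
            "a1": df["A1"].astype(str),
            "a2": df["A2"].astype(str),
            "z": z,
            "p": p_expected,
            "n": df["N"] if "N" in df.columns else np.nan,
        }
    )
    return GwasSummary(table)


# ---------------------------------------------------------------------------
# variant panel and LD reference


def write_panel(panel: VariantPanel, path: Path | str) -> None:
    out = panel.table.rename(
        columns={"snp": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1",
                 "a2": "A2", "maf": "MAF", "block": "BLOCK"}
    )
    _to_tsv(out, path)


def read_panel(path: Path | str) -> VariantPanel:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"SNP": "snp", "CHR": "chrom", "BP": "pos", "A1": "a1",
                            "A2": "a2", "MAF": "maf", "BLOCK": "block"})
    return VariantPanel(df)


def write_ld(ld: LdReference, directory: Path | str) -> None:
    """Panel TSV plus one dense text matrix per LD block."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_panel(ld.panel, directory / "panel.tsv")
    for b, R in enumerate(ld.blocks):
        np.savetxt(directory / f"ld_block_{b:05d}.txt", R, fmt=_FLOAT_FMT)


def read_ld(directory: Path | str) -> LdReference:
    directory = Path(directory)
    panel = read_panel(directory / "panel.tsv")
    n_blocks = int(panel.table["block"].max()) + 1
    blocks = [
        np.atleast_2d(np.loadtxt(directory / f"ld_block_{b:05d}.txt"))
        for b in range(n_blocks)
    ]
    return LdReference(panel, blocks)


# ---------------------------------------------------------------------------
# gene annotation (BED at the boundary, 1-based inclusive inside)


def read_annotation(path: Path | str) -> pd.DataFrame:
    """Read a BED file (chrom, start, end, gene; 0-based half-open) into the
    internal 1-based inclusive convention. Overlapping genes are permitted."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{i}: expected at least 4 BED columns")
            chrom, start, end, gene = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{i}: negative coordinate")
            if start >= end:
                raise ValueError(f"{path}:{i}: start >= end")
            chrom_val = chrom.removeprefix("chr")
            try:
                chrom_val = int(chrom_val)
            except ValueError:
                pass
            rows.append({"gene": gene, "chrom": chrom_val, "start": start + 1, "end": end})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def write_annotation_bed(annotation: pd.DataFrame, path: Path | str) -> None:
    """Write internal 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for rec in annotation.itertuples():
            fh.write(f"chr{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{rec.gene}\n")


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(expr: ExpressionMatrix, path: Path | str) -> None:
    """Genes x samples TSV with a group-label comment line above the header."""
    with open(path, "w") as fh:
        fh.write("#groups\t" + "\t".join(expr.groups.astype(str)) + "\n")
        expr.values.to_csv(fh, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_expression(path: Path | str) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#groups\t"):
            raise ValueError(f"{path}: missing '#groups' label line")
        labels = first.split("\t")[1:]
        values = pd.read_csv(fh, sep="\t", index_col="gene")
        values.index.name = None
    if len(labels) != values.shape[1]:
        raise ValueError(f"{path}: {len(labels)} group labels for {values.shape[1]} samples")
    return ExpressionMatrix(values, pd.Series(labels, index=values.columns))


# ---------------------------------------------------------------------------
# weight models


def write_weights(models: list, directory: Path | str) -> None:
    """One TSV per gene (SNP, alleles, one weight column per family) plus an
    index TSV (gene, chrom, cis interval, cv_r2 per family, best model)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for m in models:
        df = pd.DataFrame({"SNP": m.snp_ids, "A1": m.a1, "A2": m.a2})
        for fam, w in m.weights.items():
            df[f"weight_{fam}"] = w
        _to_tsv(df, directory / f"{m.gene}.wgt.tsv")
        row = {"gene": m.gene, "chrom": m.chrom, "start": m.cis_start,
               "end": m.cis_end, "best_model": m.best_model if not m.degenerate else _NA,
               "degenerate": m.degenerate}
        for fam, r2 in m.cv_r2.items():
            row[f"cv_r2_{fam}"] = r2
        index_rows.append(row)
    _to_tsv(pd.DataFrame(index_rows), directory / "weights_index.tsv")


def read_weights(directory: Path | str) -> list:
    from .datatypes import ProteinWeightModel

    directory = Path(directory)
    index = pd.read_csv(directory / "weights_index.tsv", sep="\t", na_values=[_NA])
    models = []
    for rec in index.itertuples():
        df = pd.read_csv(directory / f"{rec.gene}.wgt.tsv", sep="\t")
        fams = [c.removeprefix("weight_") for c in df.columns if c.startswith("weight_")]
        weights = {f: df[f"weight_{f}"].to_numpy(float) for f in fams}
        cv_r2 = {f: getattr(rec, f"cv_r2_{f}") for f in fams}
        degenerate = bool(rec.degenerate)
        models.append(
            ProteinWeightModel(
                gene=rec.gene, chrom=rec.chrom, cis_start=int(rec.start),
                cis_end=int(rec.end), snp_ids=df["SNP"].tolist(),
                a1=df["A1"].tolist(), a2=df["A2"].tolist(), weights=weights,
                cv_r2=cv_r2,
                best_model=None if degenerate else rec.best_model,
                degenerate=degenerate,
            )
        )
    return models


# ---------------------------------------------------------------------------
# truth records and reports (structured text)


def write_json(obj, path: Path | str) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
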