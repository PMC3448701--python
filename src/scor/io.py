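"""Tab-delimited readers and writers for expression, clinical, annotation,
copy-number and signature tables. All readers accept gzip-compressed input
transparently (by file extension), tolerate Windows line endings and strip
stray whitespace around identifiers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import (
    CopyNumberProfile,
    ExpressionMatrix,
    GeneAnnotation,
    SurvivalData,
)
from .preprocess import mad
from .signature import Signature

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "read_annotation",
    "read_copy_number",
    "read_signature",
    "write_signature",
]

_NA_TOKENS = {"", "na", "nan", "null", "none", "n/a"}


def read_expression(
    path,
    duplicates: str = "error",
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from tab-delimited text.

    The first row holds sample identifiers, the first column gene
    identifiers, the body numeric log-scale values.

    Parameters
    ----------
    duplicates : {"error", "collapse"}
        Policy for repeated gene identifiers: raise (default; distinct
        probesets are expected to carry distinct ids) or keep only the
        max-MAD row per identifier.
    missing : {"error", "impute_mean"}
        Policy for NA-like body cells: raise naming the cell (default) or
        impute with the gene's row mean.

    Raises
    ------
    ValueError
        On non-numeric body cells (naming gene and sample), duplicate
        sample identifiers, or duplicate gene identifiers under the strict
        policy.
    """
    if duplicates not in ("error", "collapse"):
        raise ValueError("duplicates must be 'error' or 'collapse'")
    if missing not in ("error", "impute_mean"):
        raise ValueError("missing must be 'error' or 'impute_mean'")
    raw = pd.read_csv(
        path, sep="\t", header=None, dtype=str, compression="infer",
        skip_blank_lines=True,
    )
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValueError("expression file needs a header row and at least one gene row")
    sample_ids = [str(s).strip() for s in raw.iloc[0, 1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ValueError(f"duplicate sample id {dup!r} in header")
    gene_ids = [str(g).strip() for g in raw.iloc[1:, 0]]
    body = raw.iloc[1:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce").to_numpy(float)
    bad = ~np.isfinite(numeric)
    if bad.any():
        gi, si = map(int, np.argwhere(bad)[0])
        cell = body.iat[gi, si]
        token = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
        if token.lower() not in _NA_TOKENS:
            raise ValueError(
                f"non-numeric value {token!r} at gene {gene_ids[gi]!r}, "
                f"sample {sample_ids[si]!r}"
            )
        if missing == "error":
            raise ValueError(
                f"missing value at gene {gene_ids[gi]!r}, sample "
                f"{sample_ids[si]!r} (pass missing='impute_mean' to impute)"
            )
        row_mean = np.nanmean(np.where(bad, np.nan, numeric), axis=1)
        if not np.all(np.isfinite(row_mean)):
            g = gene_ids[int(np.flatnonzero(~np.isfinite(row_mean))[0])]
            raise ValueError(f"gene {g!r} has no observed values to impute from")
        numeric = np.where(bad, row_mean[:, None], numeric)
    if len(set(gene_ids)) != len(gene_ids):
        if duplicates == "error":
            dup = next(g for g in gene_ids if gene_ids.count(g) > 1)
            raise ValueError(
                f"duplicate gene id {dup!r} (pass duplicates='collapse' to "
                "keep the max-MAD row per id)"
            )
        row_mad = mad(numeric, axis=1)
        best: dict[str, int] = {}
        for i, g in enumerate(gene_ids):
            if g not in best or row_mad[i] > row_mad[best[g]]:
                best[g] = i
        keep = sorted(best.values())
        gene_ids = [gene_ids[i] for i in keep]
        numeric = numeric[keep]
    return ExpressionMatrix(gene_ids, sample_ids, numeric)


def write_expression(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(
    path,
    time_col: str = "time",
    event_col: str = "event",
    sample_col: str | None = None,
) -> SurvivalData:
    """Read a clinical table into survival data.

    ``sample_col`` defaults to the first column. Extra covariate columns
    are ignored here; read them separately with pandas if needed.
    """
    df = pd.read_csv(path, sep="\t", compression="infer")
    df.columns = [str(c).strip() for c in df.columns]
    if sample_col is None:
        sample_col = df.columns[0]
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"clinical table has no column {col!r} (columns: {list(df.columns)})")
    return SurvivalData(
        [str(s).strip() for s in df[sample_col]],
        pd.to_numeric(df[time_col], errors="raise").to_numpy(float),
        pd.to_numeric(df[event_col], errors="raise").to_numpy(),
    )


def read_annotation(
    path,
    gene_col: str = "gene_id",
    symbol_col: str = "symbol",
    chromosome_col: str = "chromosome",
    category_col: str = "category",
) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", compression="infer", dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    if gene_col not in df.columns:
        raise ValueError(f"annotation table has no column {gene_col!r}")
    out = pd.DataFrame({"gene_id": df[gene_col].str.strip()})
    for src, dst in (
        (symbol_col, "symbol"),
        (chromosome_col, "chromosome"),
        (category_col, "category"),
    ):
        out[dst] = df[src].str.strip() if src in df.columns else ""
    return GeneAnnotation(out)


def read_copy_number(path) -> CopyNumberProfile:
    df = pd.read_csv(path, sep="\t", compression="infer")
    df.columns = [str(c).strip() for c in df.columns]
    return CopyNumberProfile(df)


def read_signature(path, name: str | None = None) -> Signature:
    """Read a two-column (gene_id, direction in {good, poor}) signature."""
    df = pd.read_csv(path, sep="\t", compression="infer", dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    if df.shape[1] < 2:
        raise ValueError("signature file needs gene and direction columns")
    genes = df.iloc[:, 0].str.strip()
    dirs = df.iloc[:, 1].str.strip().str.lower()
    bad = ~dirs.isin(["good", "poor"])
    if bad.any():
        raise ValueError(
            f"invalid direction {dirs[bad].iloc[0]!r} for gene {genes[bad].iloc[0]!r}"
        )
    return Signature(
        good_genes=genes[dirs == "good"].tolist(),
        poor_genes=genes[dirs == "poor"].tolist(),
        name=name or "signature",
    )


def write_signature(sig: Signature, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdirection\n")
        for g in sig.good_genes:
            fh.write(f"{g}\tgood\n")
        for g in sig.poor_genes:
            fh.write(f"{g}\tpoor\n")
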