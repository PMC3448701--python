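"""Variance filtering, robust per-gene scaling and copy-number calls."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datamodel import CopyNumberProfile, ExpressionMatrix

__all__ = ["mad", "mad_filter", "normalize_center_scale", "call_copy_number"]

# Copy-number call thresholds on the rescaled log2 axis where -1 anchors 1N.
# "below" is read strictly: a value exactly at a threshold takes the
# less-severe call.
COPY_LOSS_LOG2 = -0.7
DELETION_LOG2 = -1.5


def mad(x: np.ndarray, axis=None) -> np.ndarray:
    """Median absolute deviation, raw (no 1.4826 consistency factor).

    The raw MAD is used both for variance filtering (where any positive
    scaling of the statistic leaves the ranking unchanged) and for per-gene
    scaling, so a normalized row has median 0 and raw MAD 1.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


def mad_filter(m: ExpressionMatrix, discard_fraction: float = 0.20) -> ExpressionMatrix:
    """Drop the lowest-variability genes by median absolute deviation.

    Retains the ``ceil((1 - discard_fraction) * n_genes)`` genes with the
    largest MAD across samples. Ties at the cutoff are broken by input order
    (the earlier row wins), which makes the filter deterministic.

    Parameters
    ----------
    m : ExpressionMatrix
    discard_fraction : float in [0, 1)
        Fraction of genes to discard; 0.20 drops the bottom fifth, the usual
        background-removal setting for standard arrays (platforms with a
        large background peak may warrant ~0.30).
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    if m.n_genes == 0:
        raise ValueError("cannot MAD-filter an empty matrix")
    keep = math.ceil((1.0 - discard_fraction) * m.n_genes)
    gene_mad = mad(m.values, axis=1)
    # stable sort on descending MAD keeps input order among exact ties
    order = np.argsort(-gene_mad, kind="stable")[:keep]
    order.sort()  # preserve original row order in the output
    return ExpressionMatrix(
        [m.gene_ids[i] for i in order],
        list(m.sample_ids),
        m.values[order],
        allow_missing=m.allow_missing,
    )


def normalize_center_scale(
    m: ExpressionMatrix, gene_subset=None
) -> ExpressionMatrix:
    """Median-center each gene and divide by its MAD.

    After the transform every returned row has median 0 and raw MAD 1, which
    puts genes on a common robust scale before they are summed into a
    multi-gene score.

    Parameters
    ----------
    gene_subset : list of gene ids, optional
        Restrict the output to these genes (default: all genes).
    """
    sub = m if gene_subset is None else m.subset_genes(gene_subset)
    med = np.median(sub.values, axis=1, keepdims=True)
    scale = np.median(np.abs(sub.values - med), axis=1, keepdims=True)
    zero = np.flatnonzero(scale.ravel() == 0)
    if zero.size:
        raise ValueError(
            f"gene {sub.gene_ids[zero[0]]!r} has MAD 0 and cannot be scaled"
        )
    return ExpressionMatrix(
        list(sub.gene_ids),
        list(sub.sample_ids),
        (sub.values - med) / scale,
        allow_missing=sub.allow_missing,
    )


def call_copy_number(values) -> pd.Series | np.ndarray:
    """Call copy-number status from rescaled log2 values.

    Status is ``deletion`` for log2 < -1.5, ``copy_loss`` for
    -1.5 <= log2 < -0.7 and ``normal`` otherwise. Accepts an array of log2
    values or a :class:`CopyNumberProfile` (called row-wise).
    """
    if isinstance(values, CopyNumberProfile):
        calls = call_copy_number(values.table["log2_value"].to_numpy())
        out = values.table[["gene_id", "sample_id"]].copy()
        out["status"] = calls
        return out
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite log2 value in copy-number call")
    out = np.where(
        x < DELETION_LOG2,
        "deletion",
        np.where(x < COPY_LOSS_LOG2, "copy_loss", "normal"),
    )
    return out if x.ndim else out.item()
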