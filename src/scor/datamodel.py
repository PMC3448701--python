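"""Core in-memory containers for expression-based survival screening.

All containers are thin, validated wrappers around numpy arrays and pandas
objects. Expression values are assumed to be on a log-like scale (e.g. RMA
output); no transformation is applied on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalData",
    "GeneAnnotation",
    "CopyNumberProfile",
]


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log-scale expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique feature identifiers (gene symbols or probeset ids), one per row.
    sample_ids : list of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite expression values unless ``allow_missing`` is set, in which
        case NaN entries are tolerated (they must be imputed or the rows
        dropped before any screening).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not self.allow_missing and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx],
            allow_missing=self.allow_missing,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return ExpressionMatrix(
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
            allow_missing=self.allow_missing,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, allow_missing: bool = False) -> "ExpressionMatrix":
        return cls(
            list(frame.index), list(frame.columns), frame.to_numpy(float), allow_missing
        )


@dataclass
class SurvivalData:
    """Right-censored time-to-event outcomes keyed by sample identifier.

    ``event`` is 1 where the event was observed and 0 where the sample was
    censored; ``time`` is in the study's own units (days, months, ...).
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("times must be finite and nonnegative")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (event)")
        self.event = self.event.astype(int)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids) -> "SurvivalData":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples without survival data: {missing[:5]}")
        idx = np.array([lookup[s] for s in sample_ids], dtype=int)
        return SurvivalData(
            [self.sample_ids[i] for i in idx], self.time[idx], self.event[idx]
        )

    def aligned_to(self, m: ExpressionMatrix) -> "SurvivalData":
        """Return survival rows reordered to match the matrix sample order."""
        if set(self.sample_ids) != set(m.sample_ids):
            only_m = sorted(set(m.sample_ids) - set(self.sample_ids))
            only_s = sorted(set(self.sample_ids) - set(m.sample_ids))
            raise ValueError(
                f"sample sets differ (matrix-only: {only_m[:3]}, survival-only: {only_s[:3]})"
            )
        return self.subset(m.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event}, index=self.sample_ids
        )


@dataclass
class GeneAnnotation:
    """Per-gene annotation: symbol, chromosome, and free-text function label."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("gene_id",)
    OPTIONAL = ("symbol", "chromosome", "category")

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table).copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        for col in self.OPTIONAL:
            if col not in t.columns:
                t[col] = ""
        t["gene_id"] = t["gene_id"].astype(str)
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id in annotation: {dup!r}")
        self.table = t.reset_index(drop=True)

    def chromosome_of(self, default: str = "unknown") -> dict[str, str]:
        chrom = self.table["chromosome"].replace("", default)
        return dict(zip(self.table["gene_id"], chrom.astype(str)))

    def category_of(self) -> dict[str, str]:
        return dict(zip(self.table["gene_id"], self.table["category"].astype(str)))


@dataclass
class CopyNumberProfile:
    """Per gene x sample log2 copy-number values.

    Values are assumed rescaled so that -1, 0 and 0.585 anchor 1N, 2N and 3N
    segments respectively (log2 of copy number over 2).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table).copy()
        for col in ("gene_id", "sample_id", "log2_value"):
            if col not in t.columns:
                raise ValueError(f"copy-number table missing column {col!r}")
        t["log2_value"] = t["log2_value"].astype(float)
        if not np.all(np.isfinite(t["log2_value"])):
            raise ValueError("non-finite log2 copy-number value")
        self.table = t.reset_index(drop=True)

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.table[self.table["gene_id"] == gene_id]
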