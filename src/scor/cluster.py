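"""Gene-axis hierarchical clustering and core-signature extraction.

Selected genes are clustered on 1 - Spearman rank correlation with average
(UPGMA) linkage. The "core" of a prognostic cluster — the tight block of
mutually correlated, same-direction genes at the center of a clustered
heatmap — is formalized here as the largest dendrogram subtree whose leaves
all share one direction label and whose mean pairwise Spearman correlation
clears a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .datamodel import ExpressionMatrix

__all__ = [
    "spearman_dissimilarity",
    "spearman_correlation",
    "average_linkage",
    "Dendrogram",
    "CoreCluster",
    "extract_core_cluster",
    "write_cdt_gtr",
]


def spearman_correlation(m: ExpressionMatrix) -> np.ndarray:
    """Gene x gene Spearman rank correlation (midranks for ties)."""
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    ranks = rankdata(m.values, axis=1)
    sd = ranks.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"gene {m.gene_ids[flat[0]]!r} is constant; Spearman correlation undefined"
        )
    rho = np.corrcoef(ranks)
    return np.clip(rho, -1.0, 1.0)


def spearman_dissimilarity(m: ExpressionMatrix) -> np.ndarray:
    """1 - Spearman correlation, a symmetric dissimilarity in [0, 2]."""
    d = 1.0 - spearman_correlation(m)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """An agglomerative merge history over genes.

    ``linkage`` is a scipy-format (n-1, 4) matrix: children, merge height,
    cluster size per merge. ``leaf_order`` is the left-to-right leaf
    permutation used for heatmap-style output.
    """

    gene_ids: list[str]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.gene_ids)

    @property
    def leaf_order(self) -> np.ndarray:
        return hierarchy.leaves_list(self.linkage)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def subtree_leaves(self) -> list[np.ndarray]:
        """Leaf index sets for every internal node, in merge order."""
        n = self.n_leaves
        sets: list[np.ndarray] = []
        for i, (a, b, _h, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = np.array([a]) if a < n else sets[a - n]
            lb = np.array([b]) if b < n else sets[b - n]
            sets.append(np.sort(np.concatenate([la, lb])))
        return sets

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_ids": self.gene_ids,
                "linkage": self.linkage.tolist(),
                "leaf_order": self.leaf_order.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Dendrogram":
        obj = json.loads(text)
        return cls(obj["gene_ids"], np.asarray(obj["linkage"], dtype=float))


def average_linkage(d: np.ndarray, gene_ids) -> Dendrogram:
    """UPGMA clustering of a symmetric dissimilarity matrix.

    Inter-cluster distance is the arithmetic mean of all cross-pair
    dissimilarities; ties between candidate merges are broken toward the
    lowest-index pair (scipy's deterministic convention).
    """
    d = np.asarray(d, dtype=float)
    gene_ids = list(gene_ids)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(gene_ids):
        raise ValueError("dissimilarity shape inconsistent with gene ids")
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes to cluster")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(gene_ids, Z)


@dataclass
class CoreCluster:
    """A tight same-direction gene cluster proposed as a signature."""

    gene_ids: list[str]
    mean_pairwise_rho: float
    direction: str

    def __len__(self) -> int:
        return len(self.gene_ids)


def extract_core_cluster(
    dend: Dendrogram,
    m: ExpressionMatrix,
    directions: dict[str, str],
    min_size: int = 10,
    min_mean_rho: float = 0.5,
) -> list[CoreCluster]:
    """Extract the core prognostic cluster(s) from a gene dendrogram.

    For each direction label ("good"/"poor"), consider every dendrogram
    subtree with at least ``min_size`` leaves whose members all carry that
    label, keep those whose mean pairwise Spearman correlation is at least
    ``min_mean_rho``, and return the largest (ties broken by higher mean
    correlation, then earlier merge). Returns an empty list when nothing
    qualifies. ``directions`` typically comes from
    :meth:`scor.core.ScorResult.directions`.
    """
    rho = spearman_correlation(m.subset_genes(dend.gene_ids))
    labels = np.array([directions.get(g, "none") for g in dend.gene_ids], dtype=object)
    best: dict[str, tuple[int, float, int, np.ndarray]] = {}
    for node_i, leaves in enumerate(dend.subtree_leaves()):
        if leaves.size < min_size:
            continue
        labs = set(labels[leaves])
        if len(labs) != 1:
            continue
        direction = labs.pop()
        if direction not in ("good", "poor"):
            continue
        sub = rho[np.ix_(leaves, leaves)]
        k = leaves.size
        mean_rho = (sub.sum() - k) / (k * (k - 1))
        if mean_rho < min_mean_rho:
            continue
        key = (leaves.size, mean_rho, -node_i)
        if direction not in best or key > (
            best[direction][0],
            best[direction][1],
            -best[direction][2],
        ):
            best[direction] = (leaves.size, mean_rho, node_i, leaves)
    out = []
    for direction in ("good", "poor"):
        if direction in best:
            _size, mean_rho, _node, leaves = best[direction]
            out.append(
                CoreCluster(
                    [dend.gene_ids[i] for i in leaves], float(mean_rho), direction
                )
            )
    return out


def write_cdt_gtr(dend: Dendrogram, m: ExpressionMatrix, prefix: str) -> None:
    """Write the clustered matrix in Cluster 3.0-compatible .cdt/.gtr text.

    ``prefix`` is the output path without extension. The .gtr lists gene
    merges bottom-up with similarity = 1 - merge height; the .cdt holds the
    expression matrix in dendrogram leaf order.
    """
    sub = m.subset_genes(dend.gene_ids)
    n = dend.n_leaves

    def node_name(i: int) -> str:
        return f"GENE{i}X" if i < n else f"NODE{i - n + 1}X"

    with open(prefix + ".gtr", "w") as fh:
        for i, (a, b, h, _c) in enumerate(dend.linkage):
            fh.write(
                f"NODE{i + 1}X\t{node_name(int(a))}\t{node_name(int(b))}\t{1.0 - h:.6f}\n"
            )
    with open(prefix + ".cdt", "w") as fh:
        fh.write("GID\tNAME\tGWEIGHT\t" + "\t".join(sub.sample_ids) + "\n")
        fh.write("EWEIGHT\t\t\t" + "\t".join(["1"] * sub.n_samples) + "\n")
        for i in dend.leaf_order:
            vals = "\t".join(f"{v:.6g}" for v in sub.values[i])
            fh.write(f"GENE{i}X\t{sub.gene_ids[i]}\t1\t{vals}\n")
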