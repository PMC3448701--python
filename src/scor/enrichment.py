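"""Gene-set enrichment of candidate lists and cross-cohort overlap tables.

Enrichment of a functional gene set in a candidate prognostic list is
tested with Fisher's exact test against the background (all universe genes
not in the list), and summarized as a fold: the percentage of set members
inside the list over the percentage in the background. The module also
ships a packaged compilation of prognostic genes recurrently selected
across eight public breast-cancer cohorts (GSE1456, GSE2034, GSE2990,
GSE3494, GSE7390, GSE11121, GSE12093, NKI-295), used both as a reference
signature and as a fixture for the overlap machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneAnnotation

__all__ = [
    "EnrichmentResult",
    "OverlapTable",
    "fisher_enrichment",
    "chromosome_distribution",
    "compile_overlap",
    "load_breast_overlap_table",
    "breast_overlap_gene_lists",
]


@dataclass
class EnrichmentResult:
    """2x2 contingency counts with the enrichment fold and Fisher p.

    a: list genes in the set; b: list genes not in the set;
    c: background genes in the set; d: background genes not in the set.
    ``fold`` = (a/(a+b)) / (c/(c+d)); +inf when the set is absent from the
    background but present in the list; NaN (with ``degenerate`` True) when
    the set does not intersect the universe at all.
    """

    a: int
    b: int
    c: int
    d: int
    fold: float
    p_value: float
    degenerate: bool = False

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_enrichment(
    gene_list, gene_set, universe, alternative: str = "two-sided"
) -> EnrichmentResult:
    """Fisher exact enrichment of ``gene_set`` within ``gene_list``.

    ``gene_list`` must be a subset of ``universe``; the effective set is
    ``gene_set & universe``; the background is ``universe - gene_list``.
    The default two-sided p follows the point-probability convention (sum
    of all tables with probability <= the observed one, as in R's
    ``fisher.test``); "greater"/"less" give one-sided tests on the list.
    """
    gene_list = list(dict.fromkeys(map(str, gene_list)))
    universe_set = set(map(str, universe))
    gene_set = set(map(str, gene_set))
    if not gene_list or not universe_set:
        raise ValueError("gene list and universe must be non-empty")
    stray = [g for g in gene_list if g not in universe_set]
    if stray:
        raise ValueError(f"list genes outside the universe: {stray[:5]}")
    eff_set = gene_set & universe_set
    list_set = set(gene_list)
    background = universe_set - list_set
    a = len(list_set & eff_set)
    b = len(list_set) - a
    c = len(background & eff_set)
    d = len(background) - c
    degenerate = (a + c) == 0
    if degenerate:
        fold = float("nan")
    elif c == 0:
        fold = float("inf")
    else:
        fold = (a / (a + b)) / (c / (c + d))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(a, b, c, d, fold, float(p), degenerate)


def chromosome_distribution(
    gene_list, annotation: GeneAnnotation, universe
) -> pd.DataFrame:
    """Per-chromosome composition of a candidate list with enrichment tests.

    Returns one row per chromosome present in the universe (plus an
    "unknown" bin for unannotated genes): counts and percentages in the
    list and in the background, the enrichment fold, the raw Fisher p and
    the Bonferroni-adjusted p across tested chromosomes. Warns when the
    annotation covers less than 95% of the universe.
    """
    universe = list(dict.fromkeys(map(str, universe)))
    gene_list = list(dict.fromkeys(map(str, gene_list)))
    chrom_of = annotation.chromosome_of()
    covered = sum(1 for g in universe if chrom_of.get(g, "unknown") != "unknown")
    if covered < 0.95 * len(universe):
        warnings.warn(
            f"annotation covers only {covered}/{len(universe)} universe genes"
        )
    chroms = sorted(
        {chrom_of.get(g, "unknown") for g in universe},
        key=lambda c: (c == "unknown", len(c), c),
    )
    list_set = set(gene_list)
    bg = [g for g in universe if g not in list_set]
    rows = []
    testable = [c for c in chroms if c != "unknown"]
    for chrom in chroms:
        members = {g for g in universe if chrom_of.get(g, "unknown") == chrom}
        n_list = len(list_set & members)
        n_bg = len(members) - n_list
        row = {
            "chromosome": chrom,
            "list_count": n_list,
            "list_pct": 100.0 * n_list / len(gene_list),
            "background_count": n_bg,
            "background_pct": 100.0 * n_bg / len(bg) if bg else np.nan,
        }
        if chrom != "unknown":
            enr = fisher_enrichment(gene_list, members, universe)
            row |= {"fold": enr.fold, "p_value": enr.p_value}
        else:
            row |= {"fold": np.nan, "p_value": np.nan}
        rows.append(row)
    out = pd.DataFrame(rows)
    n_tests = len(testable)
    out["bonferroni_p"] = np.minimum(out["p_value"] * n_tests, 1.0)
    return out


@dataclass
class OverlapTable:
    """Cross-cohort membership of recurrently selected genes.

    ``table`` has one row per retained gene: binary membership per dataset,
    the row-sum ``count``, and optional direction/category annotation.
    """

    table: pd.DataFrame
    dataset_names: list[str]
    min_count: int

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def dataset_column_sums(self) -> pd.Series:
        return self.table[self.dataset_names].sum(axis=0)


def compile_overlap(
    dataset_lists: dict[str, list[str]],
    min_count: int = 3,
    directions: dict[str, str] | None = None,
    categories: dict[str, str] | None = None,
) -> OverlapTable:
    """Compile per-dataset selected-gene lists into an overlap table.

    Builds the genes x datasets binary membership matrix (exact identifier
    match), keeps genes appearing in at least ``min_count`` datasets and
    sorts rows by (direction, descending count, first-appearance order).
    Duplicate identifiers within one dataset's list are deduplicated with a
    warning.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    names = list(dataset_lists)
    order: list[str] = []
    membership: dict[str, set[str]] = {}
    for name in names:
        lst = [str(g) for g in dataset_lists[name]]
        if len(set(lst)) != len(lst):
            warnings.warn(f"duplicate genes in dataset {name!r} deduplicated")
        membership[name] = set(lst)
        for g in lst:
            if g not in order:
                order.append(g)
    rows = {
        name: [int(g in membership[name]) for g in order] for name in names
    }
    table = pd.DataFrame(rows, index=order)
    table["count"] = table[names].sum(axis=1)
    table["direction"] = [
        (directions or {}).get(g, "") for g in order
    ]
    table["category"] = [(categories or {}).get(g, "") for g in order]
    table = table[table["count"] >= min_count]
    appearance = {g: i for i, g in enumerate(order)}
    table = table.loc[
        sorted(
            table.index,
            key=lambda g: (table.at[g, "direction"], -table.at[g, "count"], appearance[g]),
        )
    ]
    return OverlapTable(table=table, dataset_names=names, min_count=min_count)


def load_breast_overlap_table() -> pd.DataFrame:
    """Load the packaged eight-cohort breast-cancer overlap compilation.

    85 genes recurrently selected (in >= 3 of 8 cohorts) by the resampled
    Cox screen, with per-cohort membership flags, the recurrence count
    (``freq``), the prognostic direction and a functional label; 58 of the
    85 are cell-division/proliferation genes.
    """
    path = resources.files("scor.data").joinpath("breast_overlap_signature.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"function": str}, keep_default_na=False)


def breast_overlap_gene_lists() -> dict[str, list[str]]:
    """Per-cohort gene lists reconstructed from the packaged overlap table."""
    df = load_breast_overlap_table()
    datasets = [c for c in df.columns if c not in ("gene", "freq", "prognosis", "function")]
    return {d: df.loc[df[d] == 1, "gene"].tolist() for d in datasets}
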