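import numpy as np
import pandas as pd
import pytest

import scor
from scor.enrichment import (
    breast_overlap_gene_lists,
    chromosome_distribution,
    compile_overlap,
    fisher_enrichment,
    load_breast_overlap_table,
)

from oracles import fisher_two_sided_enum


def _genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


class TestFisherEnrichment:
    def test_worked_example(self):
        # list of 10 with 5 set members; background 990 with 45 members:
        # fold = (5/10) / (45/990) = 11
        universe = _genes("u", 1000)
        gene_list = universe[:10]
        gene_set = universe[:5] + universe[10:55]
        res = fisher_enrichment(gene_list, gene_set, universe)
        assert (res.a, res.b, res.c, res.d) == (5, 5, 45, 945)
        assert res.fold == pytest.approx(11.0)
        assert res.p_value == pytest.approx(
            fisher_two_sided_enum(5, 5, 45, 945), abs=1e-10
        )

    def test_background_matched_composition_is_null(self):
        universe = _genes("u", 200)
        # 20% of the list and 20% of the background are set members
        gene_list = universe[:10]
        gene_set = universe[:2] + universe[10 + 0 : 10 + 38]
        res = fisher_enrichment(gene_list, gene_set, universe)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_set_disjoint_from_universe_flagged(self):
        universe = _genes("u", 50)
        res = fisher_enrichment(universe[:5], ["x1", "x2"], universe)
        assert res.degenerate
        assert res.a == 0 and res.c == 0
        assert np.isnan(res.fold)

    def test_set_absent_from_background_gives_inf_fold(self):
        universe = _genes("u", 50)
        res = fisher_enrichment(universe[:5], universe[:3], universe)
        assert res.fold == float("inf")

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fisher_enrichment(["a"], ["a"], ["b", "c"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], ["a"], ["a"])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle_random_margins(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            a, b, c, d = rng.integers(0, 50, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            universe = _genes("u", a + b + c + d)
            gene_list = universe[: a + b]
            gene_set = universe[:a] + universe[a + b : a + b + c]
            res = fisher_enrichment(gene_list, gene_set, universe)
            assert res.p_value == pytest.approx(
                fisher_two_sided_enum(a, b, c, d), abs=1e-10
            ), (a, b, c, d)

    def test_one_sided_alternative(self):
        universe = _genes("u", 100)
        res = fisher_enrichment(
            universe[:10], universe[:8] + universe[10:12], universe, alternative="greater"
        )
        assert res.p_value < 1e-6


class TestChromosomeDistribution:
    def _annotation(self, genes, chroms):
        return scor.GeneAnnotation(
            pd.DataFrame({"gene_id": genes, "chromosome": chroms})
        )

    def test_planted_chromosome_enrichment(self):
        # universe: 1000 genes, 3.6% on chr10 in the background; the list of
        # 50 contains 30% chr10 genes -> fold ~ 8.4
        rng = np.random.default_rng(0)
        universe = _genes("u", 1000)
        chr10 = set(_genes("u", 49))  # genes u0..u48
        chroms = ["10" if g in chr10 else "2" for g in universe]
        gene_list = universe[:15] + universe[900:935]  # 15 of 50 on chr10
        annot = self._annotation(universe, chroms)
        dist = chromosome_distribution(gene_list, annot, universe)
        row = dist[dist["chromosome"] == "10"].iloc[0]
        expected = fisher_enrichment(gene_list, chr10, universe)
        assert row["fold"] == pytest.approx((15 / 50) / (34 / 950))
        assert row["fold"] > 8
        assert row["p_value"] == pytest.approx(expected.p_value, abs=1e-12)

    def test_uniform_list_rarely_passes_bonferroni(self):
        rng = np.random.default_rng(1)
        universe = _genes("u", 600)
        chroms = rng.choice([str(c) for c in range(1, 23)], 600)
        annot = self._annotation(universe, chroms)
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            gene_list = list(rng.choice(universe, 40, replace=False))
            dist = chromosome_distribution(gene_list, annot, universe)
            if (dist["bonferroni_p"].dropna() < 0.05).any():
                hits += 1
        assert hits <= 0.05 * n_sim + 2

    def test_unannotated_genes_fall_in_unknown_bin(self):
        universe = _genes("u", 40)
        annot = self._annotation(universe[:38], ["1"] * 38)  # 95% coverage
        gene_list = universe[38:]
        dist = chromosome_distribution(gene_list, annot, universe)
        unknown = dist[dist["chromosome"] == "unknown"].iloc[0]
        assert unknown["list_count"] == 2
        assert dist[dist["chromosome"] == "1"]["list_count"].iloc[0] == 0

    def test_low_coverage_warns(self):
        universe = _genes("u", 40)
        annot = self._annotation(universe[:20], ["1"] * 20)
        with pytest.warns(UserWarning, match="covers only"):
            chromosome_distribution(universe[:5], annot, universe)


class TestCompileOverlap:
    def test_disjoint_lists_give_empty_table(self):
        table = compile_overlap(
            {"d1": ["a", "b"], "d2": ["c"], "d3": ["d"]}, min_count=2
        )
        assert table.table.empty

    def test_row_sums_and_sorting(self):
        lists = {
            "d1": ["a", "b", "c"],
            "d2": ["b", "c"],
            "d3": ["c", "a"],
        }
        table = compile_overlap(lists, min_count=2, directions={"a": "good", "b": "poor", "c": "poor"})
        assert table.genes == ["a", "c", "b"]  # good first, then count desc
        assert table.table.loc["c", "count"] == 3

    def test_duplicates_within_dataset_warn(self):
        with pytest.warns(UserWarning, match="deduplicated"):
            table = compile_overlap({"d1": ["a", "a", "b"], "d2": ["a"]}, min_count=1)
        assert table.table.loc["a", "count"] == 2


class TestBreastOverlapFixture:
    """The packaged eight-cohort compilation must reproduce its own printed
    summary rows when rebuilt from the per-cohort membership lists."""

    def test_recompiled_row_sums_match_freq_column(self):
        df = load_breast_overlap_table().set_index("gene")
        table = compile_overlap(breast_overlap_gene_lists(), min_count=3)
        assert set(table.genes) == set(df.index)
        for g in table.genes:
            assert table.table.loc[g, "count"] == df.loc[g, "freq"]

    def test_dataset_column_sums_match_published_row(self):
        table = compile_overlap(breast_overlap_gene_lists(), min_count=3)
        sums = table.dataset_column_sums()
        expected = {
            "GSE1456": 65, "GSE2034": 29, "GSE2990": 5, "GSE3494": 54,
            "GSE7390": 7, "GSE11121": 58, "GSE12093": 12, "NKI295": 61,
        }
        assert sums.to_dict() == expected
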