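"""TF-seeded biclustering, operon-head filtering, feeding order, upstreams."""

import numpy as np
import pandas as pd
import pytest

from regulonkit.coexpression import (
    BiclusterParams,
    correlation_profile,
    estimate_bicluster,
    extract_upstreams,
    feeding_order,
    filter_operon_heads,
)
from regulonkit.core import AnnotationSet, GeneAnnotation, Genome, revcomp
from regulonkit.simulate import make_expression, make_fitness


def _expr(rows: dict[str, list[float]]) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [f"c{j}" for j in range(df.shape[1])]
    return df


class TestCorrelationProfile:
    def test_self_correlation_is_one(self):
        df = _expr({"tf": list(range(12)), "g1": [1.0] * 6 + [2.0] * 6})
        r = correlation_profile(df, "tf")
        assert r["tf"] == pytest.approx(1.0)

    def test_exact_affine_transform_correlates_one(self):
        x = np.linspace(-2, 3, 15)
        df = _expr({"tf": list(x), "g1": list(2 * x + 1)})
        assert correlation_profile(df, "tf")["g1"] == pytest.approx(1.0)

    def test_hand_computed_anticorrelation(self):
        # 5 points padded to the 10-observation minimum with a repeat cycle
        x = [1, 2, 3, 4, 5] * 2
        y = [5, 4, 3, 2, 1] * 2
        df = _expr({"tf": x, "g1": y})
        assert correlation_profile(df, "tf")["g1"] == pytest.approx(-1.0)

    def test_too_few_shared_observations_flagged(self):
        x = list(np.arange(12.0))
        y = [1.0, 2.0] + [np.nan] * 10
        df = _expr({"tf": x, "g1": y})
        assert np.isnan(correlation_profile(df, "tf")["g1"])

    def test_zero_variance_gene_flagged(self):
        df = _expr({"tf": list(np.arange(12.0)), "g1": [3.0] * 12})
        assert np.isnan(correlation_profile(df, "tf")["g1"])

    def test_missing_tf_rejected(self):
        df = _expr({"g1": list(np.arange(12.0))})
        with pytest.raises(KeyError):
            correlation_profile(df, "tf")

    def test_pairwise_complete_missing_handling(self):
        x = np.arange(20.0)
        y = 3 * x + 2
        y[5] = np.nan
        df = _expr({"tf": list(x), "g1": list(y)})
        assert correlation_profile(df, "tf")["g1"] == pytest.approx(1.0)


class TestEstimateBicluster:
    def test_planted_recovery_with_exact_affine_genes(self):
        genes = [f"g{i:04d}" for i in range(300)]
        planted = genes[:10]
        expr, truth = make_expression(
            300, 200,
            bicluster_genes=planted,
            bicluster_conditions=list(range(120)),
            tf="g0000", sigma=0.0, seed=11, gene_ids=genes,
        )
        bic = estimate_bicluster(expr, "g0000")
        got, want = set(bic.genes), set(planted)
        assert got >= want
        assert len(got & want) / len(got | want) >= 0.8
        cond = set(bic.conditions) & set(truth.bicluster_conditions)
        assert len(cond) / len(set(bic.conditions) | set(truth.bicluster_conditions)) >= 0.7

    def test_tf_alone_when_no_structure(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(60)]
        df = pd.DataFrame(
            rng.standard_normal((60, 150)), index=genes,
            columns=[f"c{j}" for j in range(150)],
        )
        bic = estimate_bicluster(df, "g0", params=BiclusterParams(r_init=0.7))
        assert bic.genes == ["g0"]

    def test_score_in_unit_interval_and_tf_member(self):
        genes = [f"g{i:04d}" for i in range(100)]
        expr, _ = make_expression(
            100, 100, bicluster_genes=genes[:6],
            bicluster_conditions=list(range(60)), tf="g0000", sigma=0.2,
            seed=2, gene_ids=genes,
        )
        bic = estimate_bicluster(expr, "g0000")
        assert "g0000" in bic.genes
        assert 0.0 <= bic.score <= 1.0

    def test_fitness_veto_removes_incoherent_gene(self):
        genes = [f"g{i:04d}" for i in range(50)]
        planted = genes[:6]
        expr, _ = make_expression(
            50, 150, bicluster_genes=planted,
            bicluster_conditions=list(range(90)), tf="g0000", sigma=0.1,
            seed=3, gene_ids=genes,
        )
        # fitness coherent for all planted genes except g0003
        coherent = [g for g in planted if g != "g0003"]
        fitness, _ = make_fitness(genes, 30, coherent=coherent, sigma=0.1, seed=4)
        no_veto = estimate_bicluster(
            expr, "g0000", params=BiclusterParams(fitness_veto=False), fitness=fitness
        )
        assert "g0003" in no_veto.genes
        veto = estimate_bicluster(expr, "g0000", fitness=fitness)
        assert "g0003" not in veto.genes
        assert set(coherent) <= set(veto.genes)

    def test_monotone_in_r_init(self):
        genes = [f"g{i:04d}" for i in range(200)]
        expr, _ = make_expression(
            200, 200, bicluster_genes=genes[:12],
            bicluster_conditions=list(range(120)), tf="g0000", sigma=0.3,
            seed=11, gene_ids=genes,
        )
        sets = []
        for r in (0.5, 0.7, 0.9, 0.97):
            bic = estimate_bicluster(expr, "g0000", params=BiclusterParams(r_init=r))
            sets.append(set(bic.genes))
        for lo, hi in zip(sets, sets[1:]):
            assert hi <= lo


def _operon_toy():
    """Three adjacent same-strand genes + one isolated + a loose pair."""
    anns = AnnotationSet(
        [
            GeneAnnotation("gA", "c", 1000, 1500, "+"),
            GeneAnnotation("gB", "c", 1600, 2100, "+"),
            GeneAnnotation("gC", "c", 2200, 2700, "+"),
            GeneAnnotation("gD", "c", 5000, 5500, "-"),
            GeneAnnotation("gE", "c", 8000, 8500, "+"),
            GeneAnnotation("gF", "c", 8600, 9100, "+"),
        ]
    )
    rng = np.random.default_rng(5)
    base = rng.standard_normal(40)
    rows = {
        "gA": base,
        "gB": base + 0.05 * rng.standard_normal(40),
        "gC": base + 0.05 * rng.standard_normal(40),
        "gD": rng.standard_normal(40),
        "gE": rng.standard_normal(40),
        "gF": rng.standard_normal(40),
    }
    expr = pd.DataFrame({g: pd.Series(v) for g, v in rows.items()}).T
    expr.columns = [f"c{j}" for j in range(40)]
    return anns, expr


class TestFilterOperonHeads:
    def test_operon_collapses_to_head(self):
        anns, expr = _operon_toy()
        out = filter_operon_heads(["gA", "gB", "gC"], anns, expr, "gA", r_adj=0.8)
        assert out == ["gA"]

    def test_isolated_gene_retained(self):
        anns, expr = _operon_toy()
        assert filter_operon_heads(["gD"], anns, expr, "gA") == ["gD"]

    def test_uncorrelated_adjacent_pair_kept_apart(self):
        anns, expr = _operon_toy()
        out = filter_operon_heads(["gE", "gF"], anns, expr, "gA", r_adj=0.8)
        assert out == ["gE", "gF"]

    def test_idempotent(self):
        anns, expr = _operon_toy()
        genes = ["gA", "gB", "gC", "gD", "gE", "gF"]
        once = filter_operon_heads(genes, anns, expr, "gA")
        twice = filter_operon_heads(once, anns, expr, "gA")
        assert once == twice
        assert set(once) <= set(genes)

    def test_minus_strand_head_is_rightmost(self):
        anns = AnnotationSet(
            [
                GeneAnnotation("gA", "c", 1000, 1500, "-"),
                GeneAnnotation("gB", "c", 1600, 2100, "-"),
            ]
        )
        rng = np.random.default_rng(1)
        base = rng.standard_normal(30)
        expr = pd.DataFrame(
            {"gA": base, "gB": base + 0.01 * rng.standard_normal(30)}
        ).T
        expr.columns = [f"c{j}" for j in range(30)]
        assert filter_operon_heads(["gA", "gB"], anns, expr, "gA") == ["gB"]

    def test_large_gap_breaks_adjacency(self):
        anns, expr = _operon_toy()
        # gA-gB gap is 100 <= 200; with max_gap 50 they separate
        out = filter_operon_heads(["gA", "gB"], anns, expr, "gA", max_gap=50)
        assert out == ["gA", "gB"]

    def test_unannotated_gene_rejected(self):
        anns, expr = _operon_toy()
        with pytest.raises(KeyError, match="gZ"):
            filter_operon_heads(["gA", "gZ"], anns, expr, "gA")


class TestFeedingOrder:
    def _expr(self):
        x = np.arange(20.0)
        rng = np.random.default_rng(0)
        rows = {
            "tf": x,
            "g1": 0.9 * x + rng.standard_normal(20) * 2.0,
            "g2": -x,  # |r| = 1
            "g3": rng.standard_normal(20),
        }
        df = pd.DataFrame(rows).T
        df.columns = [f"c{j}" for j in range(20)]
        return df

    def test_sorted_by_descending_absolute_correlation(self):
        df = self._expr()
        order = feeding_order(["g1", "g2", "g3"], df, "tf")
        assert order[0] == "g2"
        assert order[-1] == "g3"

    def test_tf_first_when_present(self):
        df = self._expr()
        order = feeding_order(["g1", "g2", "tf"], df, "tf")
        assert order[0] == "tf"

    def test_equal_correlations_tie_lexicographically(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"tf": x, "gb": 2 * x, "ga": 3 * x}).T
        df.columns = [f"c{j}" for j in range(20)]
        assert feeding_order(["gb", "ga"], df, "tf") == ["ga", "gb"]

    def test_scrambled_order_is_seeded_and_reproducible(self):
        df = self._expr()
        s1 = feeding_order(["g1", "g2", "g3", "tf"], df, "tf", scramble_seed=9)
        s2 = feeding_order(["g1", "g2", "g3", "tf"], df, "tf", scramble_seed=9)
        assert s1 == s2
        assert sorted(s1) == ["g1", "g2", "g3", "tf"]


class TestExtractUpstreams:
    def test_plus_strand_window(self):
        genome = Genome.from_contigs({"c": "ACGTACGTACGTACGTACGT"})
        anns = AnnotationSet([GeneAnnotation("g", "c", 8, 12, "+")])
        recs = extract_upstreams(["g"], genome, anns, length=8)
        assert recs == [("g", "ACGTACGT")]

    def test_minus_strand_window_is_reverse_complement(self):
        seq = "AACCGGTTAACCGGTTAACC"
        genome = Genome.from_contigs({"c": seq})
        anns = AnnotationSet([GeneAnnotation("g", "c", 2, 8, "-")])
        recs = extract_upstreams(["g"], genome, anns, length=6)
        # upstream of a - gene ending at 8: bases [8, 14), reverse complemented
        assert recs == [("g", revcomp(seq[8:14]))]

    def test_truncated_at_contig_start_with_warning(self):
        genome = Genome.from_contigs({"c": "ACGTACGTACGT"})
        anns = AnnotationSet([GeneAnnotation("g", "c", 4, 8, "+")])
        with pytest.warns(UserWarning, match="truncated"):
            recs = extract_upstreams(["g"], genome, anns, length=10)
        assert recs == [("g", "ACGT")]

    def test_zero_length_upstream_skipped_with_warning(self):
        genome = Genome.from_contigs({"c": "ACGTACGT"})
        anns = AnnotationSet([GeneAnnotation("g", "c", 0, 4, "+")])
        with pytest.warns(UserWarning, match="skipped"):
            recs = extract_upstreams(["g"], genome, anns, length=10)
        assert recs == []
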