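"""Co-expression neighbourhoods, promoter scanning, candidate integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from q9pbm import pipeline
from q9pbm.iupac import IUPAC_CODES, revcomp
from q9pbm.simulate import DEFAULT_MOTIFS, simulate_expression, simulate_promoters
from q9pbm.targets import (
    CoexpressionResult,
    UnknownGeneError,
    ZeroVarianceError,
    coexpression_neighbors,
    go_tabulate,
    integrate,
    pearson_r,
    scan_promoter,
    scan_promoter_set,
)


def brute_force_scan(seq, pattern):
    """Oracle: sliding-window IUPAC matcher over both strands."""
    hits = set()
    n = len(seq)
    L = len(pattern)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(n - L + 1):
            window = s[i:i + L]
            if all(c in IUPAC_CODES[p] for c, p in zip(window, pattern)):
                if strand == "+":
                    hits.add((i, "+", window))
                else:
                    start = n - (i + L)
                    hits.add((start, "-", window))
    return hits


class TestPearson:
    def test_self_correlation(self):
        assert pearson_r([1, 2, 5], [1, 2, 5]) == pytest.approx(1.0)

    def test_exact_negative_linear(self):
        assert pearson_r((1, 2, 3), (6, 4, 2)) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=5), rng.normal(size=5)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den)

    def test_constant_sample_rejected(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestCoexpression:
    def test_depth_one_equals_all_pairs_filter(self):
        m = simulate_expression(50, [0.9, 0.7, 0.3], n_samples=120, seed=4)
        res = coexpression_neighbors(m, "query", min_r=0.4, depth=1)
        # oracle: brute-force correlation of every gene against the query
        q = m.loc["query"].to_numpy()
        expected = {
            g for g in m.index if g != "query"
            and np.corrcoef(q, m.loc[g])[0, 1] >= 0.4
        }
        assert set(res.genes()) == expected
        for gene, r, d in res.neighbors:
            assert d == 1
            assert r == pytest.approx(np.corrcoef(q, m.loc[gene])[0, 1])

    def test_chain_found_at_depth_two(self):
        # orthonormal construction: r(q,A)=0.7, r(A,B)=0.7, r(q,B)=0.49
        n = 8
        u = np.zeros((3, n))
        u[0, 0], u[1, 1], u[2, 2] = 1.0, 1.0, 1.0
        u -= u.mean(axis=1, keepdims=True)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        q = u[0]
        a = 0.7 * u[0] + np.sqrt(1 - 0.49) * u[1]
        b = 0.7 * a + np.sqrt(1 - 0.49) * u[2]
        m = pd.DataFrame([q, a, b], index=["q", "A", "B"])
        d1 = coexpression_neighbors(m, "q", min_r=0.55, depth=1)
        assert d1.genes() == ["A"]
        d2 = coexpression_neighbors(m, "q", min_r=0.55, depth=2)
        assert [(g, d) for g, _, d in d2.neighbors] == [("A", 1), ("B", 2)]

    def test_impossible_threshold_gives_empty_result(self):
        m = simulate_expression(5, [0.9], n_samples=50, seed=0)
        res = coexpression_neighbors(m, "query", min_r=1.0 + 1e-9)
        assert res.neighbors == []

    def test_unknown_query_rejected(self):
        m = simulate_expression(5, [], n_samples=10, seed=0)
        with pytest.raises(UnknownGeneError):
            coexpression_neighbors(m, "nope")

    def test_negative_correlations_excluded_by_default(self):
        rng = np.random.default_rng(8)
        q = rng.normal(size=60)
        m = pd.DataFrame({"q": q, "anti": -q, "pro": q}).T
        res = coexpression_neighbors(m, "q", min_r=0.55)
        assert res.genes() == ["pro"]
        res_abs = coexpression_neighbors(m, "q", min_r=0.55, absolute=True)
        assert set(res_abs.genes()) == {"pro", "anti"}


class TestScanPromoter:
    def test_planted_gcn4_site_reported_once(self):
        proms = simulate_promoters({"g": [("tgagtca", 889)]}, seed=2)
        hits = scan_promoter(proms.records["g"])
        assert [(h.motif_name, h.position, h.strand) for h in hits] == [
            ("GCN4", 889, "+")
        ]

    def test_poly_a_sequence_has_no_hits(self):
        assert scan_promoter("A" * 1000) == []

    def test_reverse_strand_atga_hit(self):
        seq = list("A" * 1000)
        seq[100:107] = "GTCATCC"  # revcomp of GGATGAC
        hits = scan_promoter("".join(seq))
        assert len(hits) == 1
        h = hits[0]
        assert h.motif_name == "ATGA"
        assert h.strand == "-"
        assert h.matched_sequence == "GGATGAC"
        # 5'-most base of the - strand hit sits at forward index 106
        assert h.position == 1000 - 106

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            scan_promoter("ACGT" * 10)

    def test_lowercase_input_accepted(self):
        seq = ("a" * 500 + "ccacgtc" + "a" * 493).lower()
        hits = scan_promoter(seq)
        assert [h.motif_name for h in hits] == ["ACGT"]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_brute_force_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        hits = scan_promoter(seq)
        for motif in DEFAULT_MOTIFS:
            got = {
                (1000 - h.position if h.strand == "+"
                 else 1000 - h.position - len(motif.pattern) + 1,
                 h.strand, h.matched_sequence)
                for h in hits if h.motif_name == motif.name
            }
            oracle = brute_force_scan(seq, motif.pattern)
            # the scanner folds - strand palindromic duplicates onto +
            oracle = {
                (i, s, w) for (i, s, w) in oracle
                if not (s == "-" and (i, "+", revcomp(w)) in oracle)
            }
            assert got == oracle


@pytest.fixture(scope="module")
def fixture_scan():
    """Promoter hits of the packaged catalogue, synthesised and scanned."""
    annotations = pipeline.fixture_promoter_annotations()
    promoters = simulate_promoters(annotations, seed=11)
    return scan_promoter_set(promoters)


@pytest.fixture(scope="module")
def fixture_table(fixture_scan):
    return integrate(
        pipeline.fixture_coexpression(), fixture_scan,
        pipeline.fixture_gene_annotations(), denominator=85,
    )


class TestIntegrate:
    def test_candidate_catalogue_round_trip(self, fixture_scan):
        table = integrate(
            pipeline.fixture_coexpression(), fixture_scan,
            pipeline.fixture_gene_annotations(), denominator=85,
        )
        assert len(table) == 44
        assert table.totals == {"GCN4": 18, "ACGT": 21, "ATGA": 13}
        assert table.percentages == {"GCN4": 21.2, "ACGT": 24.7, "ATGA": 15.3}

    def test_rows_sorted_by_correlation(self, fixture_scan):
        table = integrate(
            pipeline.fixture_coexpression(), fixture_scan,
            pipeline.fixture_gene_annotations(), denominator=85,
        )
        rs = [row.r for row in table.rows]
        assert rs == sorted(rs, reverse=True)
        assert table.rows[0].gene_id == pipeline.QUERY_GENE

    def test_empty_hits_give_empty_table(self):
        table = integrate(pipeline.fixture_coexpression(), {},
                          pipeline.fixture_gene_annotations(), denominator=85)
        assert len(table) == 0
        assert table.totals == {"GCN4": 0, "ACGT": 0, "ATGA": 0}

    def test_dual_motif_gene_counts_once_per_class(self):
        proms = simulate_promoters(
            {"dual": [("tgagtca", 850), ("ccacgtg", 352)]}, seed=3
        )
        hits = scan_promoter_set(proms)
        coexpr = CoexpressionResult(query="q", neighbors=[("dual", 0.55, 1)])
        table = integrate(coexpr, hits, {}, denominator=85)
        assert len(table) == 1
        assert table.totals == {"GCN4": 1, "ACGT": 1, "ATGA": 0}

    def test_percentages_recompute_from_totals(self, fixture_scan):
        table = integrate(
            pipeline.fixture_coexpression(), fixture_scan,
            pipeline.fixture_gene_annotations(), denominator=85,
        )
        for m, total in table.totals.items():
            assert table.percentages[m] == pytest.approx(
                round(100.0 * total / 85, 1), abs=0.05
            )
            assert total <= len(table)

    def test_invalid_denominator_rejected(self):
        with pytest.raises(ValueError):
            integrate(pipeline.fixture_coexpression(), {}, {}, denominator=0)


class TestGoTabulate:
    def test_nutrient_reservoir_group_has_six_genes(self, fixture_table):
        groups = go_tabulate(fixture_table, pipeline.go_term_names())
        assert len(groups["GO:0045735"]) == 6
        assert set(groups["GO:0045735"]) == {
            "Os01g0762500", "Os10g0400200", "Os03g0427300",
            "Os02g0268300", "Os02g0268100", "Os05g0499100",
        }

    def test_gene_with_two_terms_listed_under_both(self, fixture_table):
        groups = go_tabulate(fixture_table, pipeline.go_term_names())
        # the glutelins GluB-4/GluB-5 are both storage proteins and
        # defense-response genes
        for gene in ("Os02g0268300", "Os02g0268100"):
            assert gene in groups["GO:0045735"]
            assert gene in groups["GO:0006952"]

    def test_empty_table_gives_empty_map(self):
        empty = integrate(pipeline.fixture_coexpression(), {},
                          pipeline.fixture_gene_annotations(), denominator=85)
        assert go_tabulate(empty, pipeline.go_term_names()) == {}
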