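"""Rank breakpoint, clustering, PWM/consensus construction, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

import q9pbm
from q9pbm.iupac import revcomp
from q9pbm.motif_discovery import (
    NoBreakpointError,
    align_and_cluster,
    build_motif_model,
    line_intersection_rank,
    rank_breakpoint,
    rank_sum_pvalue,
    select_top_probes,
)
from q9pbm.simulate import MotifSpec, SignalTable, simulate_pbm_signals


def as_table(values):
    idx = pd.Index([f"p{i}" for i in range(len(values))], name="probe_id")
    return SignalTable(pd.Series(np.asarray(values, float), index=idx))


def brute_force_breakpoint(y):
    """Oracle: exhaustive SSE scan with per-segment polyfit."""
    y = np.sort(np.asarray(y, float))[::-1]
    y = y[y > 0]
    x = np.arange(1, len(y) + 1, dtype=float)
    best, best_c = np.inf, None
    for c in range(2, len(y) - 1):
        sse = 0.0
        for lo, hi in ((0, c), (c, len(y))):
            coeff = np.polyfit(x[lo:hi], y[lo:hi], 1)
            sse += float(np.sum((np.polyval(coeff, x[lo:hi]) - y[lo:hi]) ** 2))
        if sse < best:
            best, best_c = sse, c
    return best_c, best


class TestRankBreakpoint:
    def test_exact_piecewise_linear_break_recovered(self):
        x = np.arange(1, 2001, dtype=float)
        y = np.where(x <= 100, 1000 - 5 * x, 500 - 0.01 * x)
        fit = rank_breakpoint(as_table(y))
        assert fit.break_index == 100
        assert abs(fit.cutoff_rank - 100) <= 2
        assert fit.left_slope == pytest.approx(-5.0)
        assert fit.right_slope == pytest.approx(-0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_exhaustive_sse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 600
        x = np.arange(1, n + 1, dtype=float)
        y = np.where(x <= 80, 5000 - 40 * x, 900 - 0.5 * x)
        y = y + rng.normal(0, 20, n)
        y = np.maximum(y, 1.0)
        fit = rank_breakpoint(as_table(y))
        oracle_c, oracle_sse = brute_force_breakpoint(y)
        assert fit.break_index == oracle_c
        assert fit.sse == pytest.approx(oracle_sse, rel=1e-6)

    def test_printed_line_parameters_intersect_near_published_rank(self):
        # the two published line fits of the rank curve
        rank = line_intersection_rank(
            left_intercept=50320.3, left_slope=-38.3,
            right_intercept=978.4, right_slope=-0.00657,
        )
        assert rank == 1289  # (978.4 - 50320.3) / (-38.3 + 0.00657)
        assert abs(rank - 1286) <= 3

    def test_constant_signal_has_no_breakpoint(self):
        with pytest.raises(NoBreakpointError):
            rank_breakpoint(as_table(np.full(100, 7.0)))

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            rank_breakpoint(as_table([5, 4, 3, 2, 1]))


class TestSelectTopProbes:
    def test_cutoff_one_returns_single_brightest_kmer(self, toy_design):
        table = simulate_pbm_signals(toy_design, [], baseline=100.0,
                                     noise_sigma=0.4, seed=3)
        top = select_top_probes(table, toy_design, 1)
        assert len(top) == 1
        km = toy_design.probes[
            toy_design.probes.category.isin(["kmer", "replicate"])
        ]
        best = table.intensities[km.probe_id].max()
        assert top[0][1] == best

    def test_replicates_collapse_to_canonical_kmer(self, toy_design):
        table = simulate_pbm_signals(toy_design, [], baseline=100.0,
                                     noise_sigma=0.4, seed=3)
        n_probes = toy_design.probes.category.isin(["kmer", "replicate"]).sum()
        top = select_top_probes(table, toy_design, int(n_probes))
        kmers = [k for k, _ in top]
        assert len(kmers) == len(set(kmers)) == 32
        # collapsed intensity is the max over duplicate spots
        km = toy_design.probes[
            toy_design.probes.category.isin(["kmer", "replicate"])
        ].merge(table.intensities.rename("intensity"),
                left_on="probe_id", right_index=True)
        expected = km.groupby("canonical_kmer")["intensity"].max()
        for kmer, inten in top:
            assert inten == expected[kmer]

    def test_cutoff_beyond_probe_count_rejected(self, toy_design):
        table = simulate_pbm_signals(toy_design, [], baseline=100.0,
                                     noise_sigma=0.0, seed=0)
        with pytest.raises(ValueError):
            select_top_probes(table, toy_design, 10_000)


class TestClustering:
    def test_identical_kmers_form_one_cluster_at_offset_zero(self):
        top = [("TGAGTCAAA", 100.0 - i) for i in range(5)]
        clusters = align_and_cluster(top, max_motifs=3, min_cluster=1)
        assert len(clusters) == 1
        assert len(clusters[0]) == 5
        assert all(rot == 0 and strand == 1
                   for _, rot, strand, _ in clusters[0].members)

    def test_dissimilar_kmers_split_into_clusters(self):
        # >3 mismatches at every circular offset and strand
        a, b = "AAAAAAAAA", "CGCGCGCGC"
        clusters = align_and_cluster([(a, 10.0), (b, 9.0)],
                                     max_motifs=2, min_cluster=1)
        assert len(clusters) == 2
        assert {c.members[0][0] for c in clusters} == {a, b}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_and_cluster([])


class TestMotifModel:
    def _noiseless_models(self, design, motifs):
        table = simulate_pbm_signals(design, motifs, baseline=500.0,
                                     noise_sigma=0.0, seed=0)
        fit = rank_breakpoint(table)
        top = select_top_probes(table, design, fit.cutoff_rank)
        clusters = align_and_cluster(top)
        return [build_motif_model(c, table, design) for c in clusters]

    def test_singleton_cluster_rejected(self, full_design):
        from q9pbm.motif_discovery import Cluster

        table = simulate_pbm_signals(full_design, [], baseline=500.0,
                                     noise_sigma=0.0, seed=0)
        cl = Cluster(anchor="TGAGTCAAA",
                     members=[("TGAGTCAAA", 0, 1, 1000.0)])
        with pytest.raises(ValueError):
            build_motif_model(cl, table, full_design)

    def test_point_mass_pwm_for_identical_members(self, full_design):
        from q9pbm.motif_discovery import Cluster

        table = simulate_pbm_signals(full_design, [], baseline=500.0,
                                     noise_sigma=0.0, seed=0)
        cl = Cluster(anchor="TGAGTCAAA",
                     members=[("TGAGTCAAA", 0, 1, 900.0)] * 4)
        model = build_motif_model(cl, table, full_design)
        assert np.allclose(model.pwm.max(axis=1), 1.0)
        assert "TGAGTCA" in model.consensus + model.consensus

    def test_planted_exact_core_recovered_with_enrichment(self, full_design):
        models = self._noiseless_models(
            full_design, [MotifSpec("ACGT", "CCACGTC", 13_715.0)]
        )
        cores = {m.core for m in models} | {revcomp(m.core) for m in models}
        assert "CCACGTC" in cores
        lead = models[0]
        assert lead.n_core_probes >= 50
        assert lead.p_value < 1e-6
        assert lead.mean_intensity == pytest.approx(500.0 + 13_715.0)

    def test_variant_pair_yields_degenerate_consensus(self, full_design):
        models = self._noiseless_models(
            full_design,
            [MotifSpec("ACGT-C", "CCACGTC", 13_715.0),
             MotifSpec("ACGT-G", "CCACGTG", 13_715.0)],
        )
        cores = {m.core for m in models} | {revcomp(m.core) for m in models}
        assert "CCACGTS" in cores

    def test_pwm_rows_sum_to_one_and_consensus_idempotent(self, full_design,
                                                          full_expected):
        from q9pbm.motif_discovery import _consensus_code

        table = simulate_pbm_signals(full_design, seed=5,
                                     expected=full_expected)
        fit = rank_breakpoint(table)
        top = select_top_probes(table, full_design, fit.cutoff_rank)
        for cluster in align_and_cluster(top):
            model = build_motif_model(cluster, table, full_design)
            assert np.allclose(model.pwm.sum(axis=1), 1.0, atol=1e-9)
            assert len(model.consensus) == model.pwm.shape[0]
            # regenerating the consensus from the stored PWM changes nothing
            assert _consensus_code(model.pwm, 0.75, 0.25) == model.consensus


class TestRankSum:
    def test_matches_exhaustive_permutation_oracle(self):
        a = np.array([12.0, 15.0, 9.0, 20.0, 14.0])
        b = np.array([8.0, 7.0, 11.0, 6.0, 10.0, 5.0, 13.0])
        # exhaustive permutation oracle for the two-sided rank-sum test
        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        n_a = len(a)
        observed = ranks[:n_a].sum()
        mu = n_a * (len(pooled) + 1) / 2
        count = total = 0
        for comb in itertools.combinations(range(len(pooled)), n_a):
            stat = ranks[list(comb)].sum()
            total += 1
            if abs(stat - mu) >= abs(observed - mu) - 1e-9:
                count += 1
        assert rank_sum_pvalue(a, b) == pytest.approx(count / total, abs=1e-9)
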