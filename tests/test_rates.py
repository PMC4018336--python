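"""Nei–Gojobori counting, windows and the directional bootstrap."""

import itertools

import numpy as np
import pytest

from defensinevo import (
    BootstrapConfig,
    CodonAlignment,
    WindowSpec,
    bootstrap_test,
    codon_diffs,
    codon_sites,
    pairwise_ng86,
    window_scan,
)
from defensinevo.genetics import SENSE_CODONS
from defensinevo.rates import _PairProfiles, _pair_ratio_matrix, jukes_cantor

from conftest import mutated_row, random_codon_row
from ng_oracle import oracle_diffs, oracle_pairwise, oracle_sites


class TestCodonSites:
    @pytest.mark.parametrize(
        "codon,s,n",
        [
            ("TTT", 1 / 3, 8 / 3),
            ("ATG", 0.0, 3.0),
            ("GGG", 1.0, 2.0),
        ],
    )
    def test_worked_examples(self, codon, s, n):
        got = codon_sites(codon)
        assert got == pytest.approx((s, n), abs=1e-12)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            assert codon_sites(codon) == pytest.approx(oracle_sites(codon), abs=1e-12)

    def test_site_total_accounts_for_stop_neighbors(self):
        # S + N = 3 - (stop-creating changes)/3 for every sense codon
        from defensinevo.genetics import codon_neighbors, is_stop

        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            n_stop = sum(1 for _, mut in codon_neighbors(codon) if is_stop(mut))
            assert s + n == pytest.approx(3.0 - n_stop / 3.0, abs=1e-12)

    def test_undefined_for_stop_and_ambiguity(self):
        assert codon_sites("TAA") is None
        assert codon_sites("ANA") is None
        assert codon_sites("A-A") is None


class TestCodonDiffs:
    @pytest.mark.parametrize(
        "c1,c2,sd,nd",
        [
            ("TTT", "TTC", 1.0, 0.0),
            ("TTT", "TTT", 0.0, 0.0),
            ("TTT", "GTA", 0.5, 1.5),  # two pathways: (1,1) and (0,2)
        ],
    )
    def test_worked_examples(self, c1, c2, sd, nd):
        assert codon_diffs(c1, c2) == pytest.approx((sd, nd), abs=1e-12)

    def test_all_sense_pairs_match_oracle_and_sum_to_k(self):
        for c1, c2 in itertools.product(SENSE_CODONS, SENSE_CODONS):
            got = codon_diffs(c1, c2)
            want = oracle_diffs(c1, c2)
            assert got == pytest.approx(want, abs=1e-12)
            k = sum(a != b for a, b in zip(c1, c2))
            assert got[0] + got[1] == pytest.approx(k, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            c1, c2 = rng.choice(SENSE_CODONS, size=2)
            assert codon_diffs(c1, c2) == codon_diffs(c2, c1)


class TestPairwise:
    def test_identical_rows_give_zero_rates(self):
        row = random_codon_row(np.random.default_rng(0), 20)
        r = pairwise_ng86(row, row)
        assert r.defined and r.Ka == 0.0 and r.Ks == 0.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = random_codon_row(rng, 15)
        b = mutated_row(rng, a, 8)
        ra, rb = pairwise_ng86(a, b), pairwise_ng86(b, a)
        assert (ra.Ka, ra.Ks, ra.S, ra.N) == (rb.Ka, rb.Ks, rb.S, rb.N)

    def test_saturated_synonymous_proportion_is_undefined(self):
        # single Phe codon pair differing synonymously: Sd=1 over S=1/3
        r = pairwise_ng86("TTT", "TTC")
        assert not r.defined
        assert "3/4" in r.reason

    def test_gapped_and_ambiguous_codons_are_skipped(self):
        a = "TTT" + "AAA" + "GGG"
        b = "TT-" + "AAA" + "GNG"
        r = pairwise_ng86(a, b)
        assert r.n_codons == 1  # only the AAA column survives

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            a = random_codon_row(rng, 10)
            b = mutated_row(rng, a, int(rng.integers(0, 9)))
            got = pairwise_ng86(a, b)
            want = oracle_pairwise(a, b)
            if want is None:
                assert not got.defined
            else:
                assert got.defined
                assert (got.Ka, got.Ks) == pytest.approx(want, abs=1e-10)
            checked += 1

    def test_jukes_cantor_boundary(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.5) == pytest.approx(0.75 * np.log(3), abs=1e-12)


class TestWindows:
    def test_window_arithmetic_10_by_5_over_100_columns(self):
        spans = WindowSpec(size=10, step=5).windows(100)
        assert len(spans) == 19
        assert spans[0] == (1, 10) and spans[-1] == (91, 100)
        starts = [s for s, _ in spans]
        assert np.all(np.diff(starts) == 5)

    def test_trailing_short_window_dropped(self):
        spans = WindowSpec(size=10, step=5).windows(97)
        assert spans[-1] == (86, 95)

    def test_identical_sequences_have_full_identity_and_undefined_ratio(self):
        row = random_codon_row(np.random.default_rng(3), 40)
        aln = CodonAlignment([("a", row), ("b", row), ("c", row)])
        stats = window_scan(aln)
        for st in stats:
            assert st.identity == pytest.approx(100.0)
            assert st.avg_Ka == 0.0 and st.avg_Ks == 0.0
            assert np.isnan(st.avg_KaKs) and st.n_pairs_used == 0

    def test_scan_requires_two_sequences(self):
        row = random_codon_row(np.random.default_rng(4), 30)
        with pytest.raises(ValueError):
            window_scan(CodonAlignment([("only", row)]))

    def test_window_rates_agree_with_pairwise_calls(self, small_family):
        _, aln, _ = small_family
        prof = _PairProfiles.build(aln)
        ka, ks = prof.window_rates(31, 40)
        for p, (i, j) in enumerate(prof.pairs[:10]):
            r = pairwise_ng86(aln.records[i][1], aln.records[j][1], (31, 40))
            if r.defined:
                assert ka[p] == pytest.approx(r.Ka, abs=1e-12)
                assert ks[p] == pytest.approx(r.Ks, abs=1e-12)
            else:
                assert np.isnan(ka[p]) or np.isnan(ks[p])

    def test_windows_cover_prefix_and_step_arithmetically(self, small_family):
        _, aln, _ = small_family
        stats = window_scan(aln)
        starts = [st.start for st in stats]
        assert starts[0] == 1
        assert all(b - a == 5 for a, b in zip(starts, starts[1:]))
        assert stats[-1].end <= aln.n_aa_columns


class TestBootstrap:
    def _toy_matrix(self, n, value, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        mat = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = value + jitter * rng.normal()
        return mat

    def test_symmetric_replicates_give_half(self):
        # all pair ratios exactly 1 -> every replicate mean is 1, sd = 0
        mat = self._toy_matrix(8, 1.0)
        p, direction, m, sd = bootstrap_test(mat, 1.0, BootstrapConfig(replicates=100, seed=1))
        assert sd == 0.0 and m == 1.0
        assert p == 0.5

    def test_degenerate_normal_above_one(self):
        mat = self._toy_matrix(8, 2.0)
        p, direction, m, sd = bootstrap_test(mat, 2.0, BootstrapConfig(replicates=100, seed=1))
        assert direction == "greater" and sd == 0.0
        assert p == 0.0

    def test_degenerate_normal_below_one(self):
        mat = self._toy_matrix(8, 0.25)
        p, direction, *_ = bootstrap_test(mat, 0.25, BootstrapConfig(replicates=100, seed=1))
        assert direction == "less" and p == 0.0

    def test_direction_follows_observed_average(self):
        mat = self._toy_matrix(8, 1.5, jitter=0.2, seed=5)
        p_g, d_g, *_ = bootstrap_test(mat, 1.5, BootstrapConfig(replicates=200, seed=2))
        assert d_g == "greater"
        mat = self._toy_matrix(8, 0.6, jitter=0.2, seed=6)
        p_l, d_l, *_ = bootstrap_test(mat, 0.6, BootstrapConfig(replicates=200, seed=2))
        assert d_l == "less"
        assert 0.0 <= p_g <= 1.0 and 0.0 <= p_l <= 1.0

    def test_seeded_scan_is_reproducible(self, small_family):
        _, aln, _ = small_family
        boot = BootstrapConfig(replicates=50, seed=9)
        s1 = window_scan(aln, WindowSpec(), boot)
        s2 = window_scan(aln, WindowSpec(), boot)
        assert [st.p_value for st in s1] == [st.p_value for st in s2]
        assert [st.boot_mean for st in s1] == [st.boot_mean for st in s2]

    def test_all_undefined_matrix_gives_nan_p(self):
        mat = np.full((6, 6), np.nan)
        p, direction, m, sd = bootstrap_test(mat, 1.2, BootstrapConfig(replicates=10, seed=0, max_redraws=5))
        assert np.isnan(p) and np.isnan(m)


class TestGeneratorRecovery:
    def test_mature_windows_exceed_signal_windows(self, small_family):
        from defensinevo.rates import region_means

        cfg, aln, _ = small_family
        stats = window_scan(aln)
        rm = region_means(stats, cfg.partition)
        assert rm["mature"] > rm["signal"]

    def test_ks_saturation_is_monotone_in_branch_length(self):
        from defensinevo import SimConfig, simulate_family

        means = []
        for bl in (0.1, 0.25, 0.5):
            vals = []
            for seed in (11, 12, 13):
                cfg = SimConfig(
                    seed=seed, branch_length=bl,
                    region_omegas={"signal": 1.0, "prosegment": 1.0, "mature": 1.0},
                )
                aln, _ = simulate_family(cfg)
                st = window_scan(aln, WindowSpec(size=94, step=94))[0]
                vals.append(st.avg_Ks)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
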