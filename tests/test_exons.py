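"""Cassette-exon counting, filters, Fisher testing and BY correction."""

import math

import numpy as np
import pytest

from beadsplice.exons import (
    ExonCounts,
    correct_by,
    count_exon_support,
    eligible_reads,
    flag_significant,
    is_alternative,
    run_exon_tests,
    summarize,
)
from beadsplice.exons import test_exon as exon_test
from beadsplice.io import ExonId

from conftest import make_read


# --- independent oracles ---------------------------------------------------


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of tables with the same
    margins, summing probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


def by_oracle(pvals):
    """Benjamini-Yekutieli by direct formula: p_(i) * m * c(m) / i, enforced
    monotone from the largest rank down, capped at 1."""
    m = len(pvals)
    cm = sum(1.0 / j for j in range(1, m + 1))
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m * cm / rank)
        adj[i] = min(1.0, running)
    return adj


# --- the hand-built 12-read fixture ---------------------------------------

EXON = ExonId("chr1", 500, 600, "+")


def fixture_reads(group="g1", offset=0):
    reads = []

    def add(rid, blocks):
        reads.append(
            make_read(read_id=f"{group}{offset}_{rid}", group=group, blocks=blocks)
        )

    for i in range(6):  # A: exon block with both flanking introns
        add(f"a{i}", ((100, 200), (500, 600), (800, 900)))
    for i in range(2):  # B: left splice site + right read end on the exon
        add(f"b{i}", ((100, 200), (500, 550)))
    add("c0", ((520, 600), (800, 900)))  # C: right splice site + left end on exon
    for i in range(3):  # D: intron spans the exon
        add(f"d{i}", ((100, 200), (800, 900)))
    return reads


class TestCountExonSupport:
    def test_manual_enumeration(self):
        counts = count_exon_support(EXON, fixture_reads())
        assert (counts.A, counts.B, counts.C, counts.D, counts.E) == (6, 2, 1, 3, 0)
        assert counts.left_psi == pytest.approx(8 / 11)
        assert counts.right_psi == pytest.approx(7 / 10)
        assert counts.psi == pytest.approx(0.75)

    def test_full_exon_block_with_introns_is_A(self):
        r = make_read(blocks=((100, 200), (500, 600), (800, 900)))
        c = count_exon_support(EXON, [r])
        assert (c.A, c.total) == (1, 1)

    def test_spanning_intron_is_D(self):
        r = make_read(blocks=((400, 450), (650, 700)))  # intron (451, 649) spans exon
        c = count_exon_support(EXON, [r])
        assert c.D == 1

    def test_terminal_exon_overlap_is_E(self):
        # read overlaps the exon but supports neither splice site
        r = make_read(blocks=((550, 950),))
        r2 = make_read(read_id="r2", blocks=((550, 700), (800, 900)))
        c = count_exon_support(EXON, [r, r2])
        assert c.E == 2

    def test_conservation_every_overlapping_read_counted_once(self, rng):
        # random spliced reads: total A+B+C+D+E equals overlap count
        reads = []
        for i in range(200):
            pos = np.sort(rng.choice(np.arange(1, 1200), size=6, replace=False))
            blocks = ((int(pos[0]), int(pos[1])), (int(pos[2]), int(pos[3])), (int(pos[4]), int(pos[5])))
            if any(blocks[j + 1][0] - blocks[j][1] < 2 for j in range(2)):
                continue
            reads.append(make_read(read_id=f"r{i}", blocks=blocks))
        c = count_exon_support(EXON, reads)
        n_overlap = sum(
            1 for r in reads if not (r.span[1] < EXON.start or r.span[0] > EXON.end)
        )
        assert c.total == n_overlap

    def test_other_chromosome_ignored(self):
        r = make_read(blocks=((500, 600),), chrom="chr9")
        assert count_exon_support(EXON, [r]).total == 0


class TestEligibleReads:
    def test_unspliced_dropped_spliced_kept(self):
        spliced = make_read(read_id="s", blocks=((1, 10), (20, 30)))
        unspliced = make_read(read_id="u", blocks=((1, 30),))
        assert list(eligible_reads([spliced, unspliced])) == [spliced]

    def test_consensus_flags_respected(self):
        reads = [
            make_read(read_id="good", blocks=((1, 10), (20, 30))),
            make_read(read_id="bad", blocks=((1, 10), (20, 30))),
        ]
        kept = list(eligible_reads(reads, {"good": True, "bad": False}))
        assert [r.read_id for r in kept] == ["good"]

    def test_mixed_fixture_manual_enumeration(self):
        reads = fixture_reads()  # all spliced except... all have introns
        plus_unspliced = reads + [make_read(read_id="u", blocks=((100, 900),))]
        assert list(eligible_reads(plus_unspliced)) == reads


class TestIsAlternative:
    def test_too_few_reads_and_monomorphic(self):
        ok, reason = is_alternative(ExonCounts(EXON, A=9))
        assert not ok and "9 < 10" in reason

    def test_fixture_passes_all_filters(self):
        ok, reason = is_alternative(ExonCounts(EXON, 6, 2, 1, 3, 0))
        assert ok and reason == ""

    def test_purity_filter(self):
        ok, reason = is_alternative(ExonCounts(EXON, 8, 0, 0, 8, 5))
        assert not ok and "purity" in reason  # 16/21 ~ 0.762 < 0.8

    def test_psi_bounds(self):
        # leftPSI = rightPSI = 1: no skipping evidence at all
        ok, reason = is_alternative(ExonCounts(EXON, A=20))
        assert not ok and "PSI" in reason


class TestTestExon:
    def test_p_matches_hypergeometric_enumeration(self):
        c1 = ExonCounts(EXON, A=9, D=3)
        c2 = ExonCounts(EXON, A=2, D=10)
        res = exon_test(c1, c2)
        assert res.tested
        assert res.p == pytest.approx(fisher_oracle([[9, 3], [2, 10]]), rel=1e-9)

    def test_random_tables_match_oracle(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(100):
            t = rng.integers(0, 40, size=4)
            table = [[int(t[0]), int(t[1])], [int(t[2]), int(t[3])]]
            if sum(table[0]) == 0 or sum(table[1]) == 0:
                continue
            p = fisher_exact(table, alternative="two-sided")[1]
            assert p == pytest.approx(fisher_oracle(table), rel=1e-7, abs=1e-12)

    def test_identical_groups_p_one_delta_zero(self):
        c = ExonCounts(EXON, A=10, D=10)
        res = exon_test(c, c)
        assert res.tested and res.p == pytest.approx(1.0)
        assert res.delta_psi == 0

    def test_expected_count_boundary(self):
        # groups sized so exactly 2 of 4 expected counts reach 5 -> untested
        c1 = ExonCounts(EXON, A=1, D=9)
        c2 = ExonCounts(EXON, A=1, D=9)
        res = exon_test(c1, c2)  # expected: (1, 9, 1, 9) -> only 2 cells >= 5
        assert not res.tested and "expected" in res.filter_reason

    def test_underpowered_group_untested(self):
        res = exon_test(ExonCounts(EXON, A=6, D=6), ExonCounts(EXON, A=4, D=3))
        assert not res.tested

    def test_group_swap_antisymmetry(self):
        c1 = ExonCounts(EXON, A=9, D=3)
        c2 = ExonCounts(EXON, A=4, D=8)
        r12 = exon_test(c1, c2)
        r21 = exon_test(c2, c1)
        assert r12.delta_psi == pytest.approx(-r21.delta_psi)
        assert r12.p == pytest.approx(r21.p)


class TestCorrectBY:
    def _results(self, pvals):
        out = []
        for i, p in enumerate(pvals):
            c = ExonCounts(EXON, A=10, D=10)
            from beadsplice.exons import ExonTestResult

            out.append(
                ExonTestResult(EXON, f"g{i}", c, c, 0.5, 0.5, 0.0, p, tested=True)
            )
        return out

    def test_single_p_unchanged(self):
        assert correct_by(self._results([0.03]))[0].fdr == pytest.approx(0.03)

    def test_matches_closed_form(self):
        pvals = [0.01, 0.02, 0.03, 0.04]
        got = [r.fdr for r in correct_by(self._results(pvals))]
        assert got == pytest.approx(by_oracle(pvals))

    def test_all_ones_stay_one(self):
        assert [r.fdr for r in correct_by(self._results([1.0] * 5))] == [1.0] * 5

    def test_by_geq_bh_geq_raw(self, rng):
        from statsmodels.stats.multitest import multipletests

        pvals = rng.random(30).tolist()
        by = correct_by(self._results(pvals))
        bh = multipletests(pvals, method="fdr_bh")[1]
        for r, p, b in zip(by, pvals, bh):
            assert r.fdr >= b - 1e-12 >= p - 1 - 1e-12
            assert b >= p - 1e-12


class TestSummarize:
    def test_zero_significant(self):
        res = correct_by(TestCorrectBY()._results([0.9] * 10))
        s = summarize(flag_significant(res))
        assert s.n_tested == 10 and s.percent_significant == 0.0

    def test_three_of_sixteen(self):
        from dataclasses import replace

        res = TestCorrectBY()._results([0.5] * 16)
        res = [replace(r, fdr=0.01 if i < 3 else 0.5, delta_psi=0.4) for i, r in enumerate(res)]
        s = summarize(flag_significant(res))
        assert s.percent_significant == pytest.approx(18.75)

    def test_permutation_invariant(self, rng):
        from dataclasses import replace

        res = TestCorrectBY()._results(list(rng.random(12)))
        res = correct_by(res)
        res = flag_significant(res)
        perm = [res[i] for i in rng.permutation(len(res))]
        assert summarize(perm).percent_significant == summarize(res).percent_significant

    def test_empty_undefined(self):
        assert summarize([]).percent_significant is None


class TestEndToEnd:
    def test_strong_shift_detected(self, rng):
        from beadsplice.sim import simulate_cassette_read_models

        records = simulate_cassette_read_models(8, 60, 0.15, 0.85, rng)
        results = run_exon_tests(records, "g1", "g2")
        assert all(r.tested for r in results)
        assert sum(r.significant for r in results) >= 7
        for r in results:
            assert 0.5 <= r.delta_psi <= 0.9

    def test_type_one_error_controlled_under_null(self, rng):
        # both groups from one inclusion rate; BY keeps false positives <= 5%
        from beadsplice.sim import simulate_cassette_read_models

        psi = rng.uniform(0.2, 0.8, size=1000)
        records = simulate_cassette_read_models(1000, 20, psi, psi, rng)
        results = run_exon_tests(records, "g1", "g2")
        tested = [r for r in results if r.tested]
        assert len(tested) > 500
        frac = sum(r.fdr < 0.05 for r in tested) / len(tested)
        assert frac <= 0.05

    def test_delta_psi_recovered_within_binomial_error(self, rng):
        from beadsplice.sim import simulate_cassette_read_models

        records = simulate_cassette_read_models(50, 100, 0.25, 0.75, rng)
        results = run_exon_tests(records, "g1", "g2")
        deltas = [r.delta_psi for r in results if r.tested]
        assert len(deltas) == 50
        assert np.mean(deltas) == pytest.approx(0.5, abs=0.1)
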