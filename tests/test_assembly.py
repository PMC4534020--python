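"""Fingerprint assembly: Sulston score, clustering, stepwise merging, MTP, stats."""

import itertools
import math
import random

import numpy as np
import pytest
from scipy.stats import binom

from wgpmap.assembly import (
    AssemblyParams,
    Contig,
    ClonePlacement,
    Fingerprint,
    RoundSummary,
    assembly_stats,
    build_contigs,
    filter_bacs_by_tag_count,
    select_final_cutoff,
    select_mtp,
    stepwise_assembly,
    sulston_log10,
    sulston_score,
)
from wgpmap.errors import EmptyInputError, InvalidParameterError


def fp(bac_id, tags):
    return Fingerprint(bac_id=bac_id, tags=frozenset(tags))


class TestTagCountFilter:
    def test_paper_thresholds_from_mean(self):
        # dataset mean 20.6 -> keep iff 7 <= n_tags <= 51
        counts = [20, 21, 20, 21, 21]  # mean 20.6
        fps = [fp(f"b{i}", range(100 * i, 100 * i + c)) for i, c in enumerate(counts)]
        res = filter_bacs_by_tag_count(fps)
        assert (res.lower, res.upper) == (7, 51)

    def test_identical_counts_exclude_nothing(self):
        fps = [fp(f"b{i}", range(10 * i, 10 * i + 9)) for i in range(10)]
        res = filter_bacs_by_tag_count(fps)
        assert not res.excluded

    def test_explicit_thresholds_on_toy_set(self):
        counts = [3, 6, 7, 20, 30, 51, 52, 60, 10, 40]
        fps = [fp(f"b{i}", range(1000 * i, 1000 * i + c)) for i, c in enumerate(counts)]
        res = filter_bacs_by_tag_count(fps, thresholds=(7, 51))
        assert len(res.kept) == 6

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            filter_bacs_by_tag_count([])


class TestSulstonScore:
    def test_no_shared_tags_scores_one(self, small_params):
        a, b = fp("a", range(10)), fp("b", range(100, 110))
        assert sulston_score(a, b, small_params) == 1.0

    def test_identical_20_tag_fingerprints_below_initial_cutoff(self):
        # motivates the stepwise assembly's 1e-75 starting point
        assert sulston_log10(20, 20, 20, 120_913) < -75

    def test_symmetry(self, small_params):
        a, b = fp("a", range(12)), fp("b", range(6, 30))
        assert sulston_score(a, b, small_params) == sulston_score(b, a, small_params)

    def test_monotone_nonincreasing_in_shared_count(self):
        scores = [sulston_log10(10, 12, m, 500) for m in range(11)]
        assert all(s2 <= s1 for s1, s2 in zip(scores, scores[1:]))

    def test_matches_scipy_binomial_tail(self):
        for n1, n2, m, G in [(5, 8, 2, 100), (10, 10, 4, 200), (20, 30, 7, 1000)]:
            q = -math.expm1(max(n1, n2) * math.log1p(-1.0 / G))
            expect = binom.sf(m - 1, min(n1, n2), q)
            got = 10 ** sulston_log10(n1, n2, m, G)
            assert got == pytest.approx(expect, rel=1e-10)

    def test_invalid_gel_length(self):
        with pytest.raises(InvalidParameterError):
            sulston_log10(5, 5, 2, 0)
        with pytest.raises(InvalidParameterError):
            sulston_log10(5, 300, 2, 100)


class TestBuildContigs:
    def test_all_singletons_when_nothing_qualifies(self, small_params):
        fps = [fp(f"b{i}", range(100 * i, 100 * i + 10)) for i in range(5)]
        contigs, singles = build_contigs(fps, 1e-10, small_params)
        assert not contigs and len(singles) == 5

    def test_three_tiled_clones_form_one_contig(self, small_params):
        # clones tiled across ~300 kb with pairwise overlaps
        a = fp("a", range(0, 20))
        b = fp("b", range(12, 32))
        c = fp("c", range(24, 44))
        contigs, singles = build_contigs([a, b, c], 1e-10, small_params)
        assert len(contigs) == 1 and contigs[0].n_members == 3 and not singles

    def test_estimated_size_uses_cb_unit(self):
        params = AssemblyParams(gel_length_G=120_913, cb_unit=5220)
        fps = [fp("a", range(0, 60)), fp("b", range(40, 100))]
        contigs, _ = build_contigs(fps, 1e-10, params)
        assert contigs[0].unique_tags == 100
        assert contigs[0].estimated_size == 522_000

    def test_partition_is_input_order_independent(self, small_params):
        rng = random.Random(5)
        fps = [fp(f"b{i:02d}", range(7 * i, 7 * i + 20)) for i in range(30)]
        contigs1, s1 = build_contigs(fps, 1e-12, small_params)
        shuffled = fps[:]
        rng.shuffle(shuffled)
        contigs2, s2 = build_contigs(shuffled, 1e-12, small_params)
        part1 = sorted(frozenset(c.member_ids) for c in contigs1)
        part2 = sorted(frozenset(c.member_ids) for c in contigs2)
        assert part1 == part2
        cb1 = {m.bac_id: m.cb_start for c in contigs1 for m in c.members}
        cb2 = {m.bac_id: m.cb_start for c in contigs2 for m in c.members}
        assert cb1 == cb2


class TestStepwiseAssembly:
    def test_ledger_length_equals_rounds(self, tiled_fingerprints, small_params):
        _model, _clones, fps, _orig, _pos = tiled_fingerprints
        result = stepwise_assembly(fps[:150], small_params)
        assert len(result.ledger) == len(small_params.cutoff_exponents)

    def test_single_round_equals_plain_clustering(self, small_params):
        params = AssemblyParams(
            gel_length_G=small_params.gel_length_G,
            cb_unit=small_params.cb_unit,
            initial_cutoff_exponent=-20,
            final_cutoff_exponent=-20,
        )
        fps = [fp(f"b{i}", range(8 * i, 8 * i + 20)) for i in range(12)]
        result = stepwise_assembly(fps, params)
        direct, _ = build_contigs(fps, 1e-20, params)
        got = sorted(frozenset(c.member_ids) for c in result.rounds[0][1])
        want = sorted(frozenset(c.member_ids) for c in direct)
        assert got == want

    def test_noise_free_assembly_recovers_tiling_paths(self, tiled_fingerprints):
        model, clones, fps, _orig, pos = tiled_fingerprints
        params = AssemblyParams(gel_length_G=len(pos), cb_unit=6311,
                                final_cutoff_exponent=-10)
        result = stepwise_assembly(fps, params)
        contigs, _ = result.state_at(select_final_cutoff(result.ledger, model.length))
        span = {c.id: (c.start, c.end) for c in clones}
        # no chimeras: members of each contig form one overlapping chain in truth
        for c in contigs:
            ivals = sorted(span[m.bac_id] for m in c.members)
            cur_end = ivals[0][1]
            for s, e in ivals[1:]:
                assert s < cur_end, f"chimeric contig {c.id}"
                cur_end = max(cur_end, e)
        # >=95% of truly co-contiged clone pairs are co-contiged in the output
        ordered = sorted(clones, key=lambda c: c.start)
        true_pairs = set()
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                if b.start >= a.end:
                    break
                if len(
                    {t for t, p in pos.items() if max(a.start, b.start) <= p < min(a.end, b.end)}
                ) >= 3:
                    true_pairs.add((a.id, b.id))
        member_of = {m.bac_id: c.id for c in contigs for m in c.members}
        hit = sum(
            1
            for a, b in true_pairs
            if member_of.get(a) is not None and member_of.get(a) == member_of.get(b)
        )
        assert hit / len(true_pairs) >= 0.95

    def test_contig_size_close_to_true_span(self, tiled_fingerprints):
        model, clones, fps, _orig, pos = tiled_fingerprints
        params = AssemblyParams(gel_length_G=len(pos), cb_unit=6311,
                                final_cutoff_exponent=-10)
        contigs, _ = build_contigs(fps, 1e-10, params)
        span = {c.id: (c.start, c.end) for c in clones}
        for c in contigs:
            lo = min(span[m.bac_id][0] for m in c.members)
            hi = max(span[m.bac_id][1] for m in c.members)
            assert abs(c.estimated_size - (hi - lo)) <= 2 * params.cb_unit * c.n_members


class TestSelectFinalCutoff:
    def _round(self, e, q, size):
        return RoundSummary(e, 10, q, 0, size)

    def test_single_round(self):
        assert select_final_cutoff([self._round(-30, 2, 100)], 100) == -30

    def test_unique_q_minimum_wins(self):
        ledger = [
            self._round(-20, 5, 100),
            self._round(-12, 1, 100),
            self._round(-10, 4, 100),
        ]
        assert select_final_cutoff(ledger, 100) == -12

    def test_tie_broken_toward_stringent(self):
        ledger = [self._round(-20, 2, 100), self._round(-15, 2, 100)]
        assert select_final_cutoff(ledger, 100) == -20

    def test_empty_ledger(self):
        with pytest.raises(EmptyInputError):
            select_final_cutoff([], 100)


def _contig_from_intervals(ivals):
    members = [
        ClonePlacement(bac_id=f"b{i}", cb_start=s, cb_end=e, n_tags=e - s)
        for i, (s, e) in enumerate(ivals)
    ]
    return Contig(
        id="T", members=members, unique_tags=10, estimated_size=10, tags=frozenset()
    )


def _exhaustive_minimal_cover(ivals):
    """Smallest subset covering [min, max) with consecutive overlap >= 1."""
    target_lo = min(s for s, _ in ivals)
    target_hi = max(e for _, e in ivals)
    for k in range(1, len(ivals) + 1):
        for combo in itertools.combinations(range(len(ivals)), k):
            sel = sorted(ivals[i] for i in combo)
            if sel[0][0] != target_lo:
                continue
            end = sel[0][1]
            ok = True
            for s, e in sel[1:]:
                if s > end - 1:
                    ok = False
                    break
                end = max(end, e)
            if ok and end >= target_hi:
                return k
    return len(ivals)


class TestMinimalTilingPath:
    def test_single_member(self):
        c = _contig_from_intervals([(0, 10)])
        assert select_mtp(c) == ["b0"]

    def test_five_clones_three_suffice(self):
        ivals = [(0, 10), (5, 14), (8, 20), (15, 26), (18, 30)]
        c = _contig_from_intervals(ivals)
        mtp = select_mtp(c)
        assert len(mtp) == 3
        assert mtp == ["b0", "b2", "b4"]

    def test_matches_exhaustive_cover_on_random_contigs(self):
        rng = random.Random(9)
        for _ in range(30):
            n = rng.randint(2, 12)
            ivals = []
            start = 0
            for _i in range(n):
                s = max(0, start - rng.randint(0, 4))
                ivals.append((s, s + rng.randint(5, 15)))
                start = ivals[-1][1]
            # ensure connectivity: clip gaps
            ivals.sort()
            fixed = [ivals[0]]
            for s, e in ivals[1:]:
                if s > fixed[-1][1] - 1:
                    s = fixed[-1][1] - 1
                fixed.append((s, max(e, s + 2)))
            c = _contig_from_intervals(fixed)
            assert len(select_mtp(c)) == _exhaustive_minimal_cover(fixed)


class TestAssemblyStats:
    def _contigs(self, sizes):
        return [
            Contig(id=f"c{i}", members=[ClonePlacement(f"b{i}", 0, 1, 1)],
                   unique_tags=1, estimated_size=s, tags=frozenset())
            for i, s in enumerate(sizes)
        ]

    def test_forced_by_definition(self):
        stats = assembly_stats(self._contigs([4e6, 3e6, 2e6, 1e6]))
        assert stats["N50"] == 3e6 and stats["L50"] == 2

    def test_single_contig(self):
        stats = assembly_stats(self._contigs([7e6]))
        assert stats["N50"] == 7e6 and stats["L50"] == 1

    def test_chromosome_coverage_percentage(self):
        # 794.8 Mb of mapped contigs on a 914 Mb chromosome
        stats = assembly_stats(self._contigs([794.8e6]), arm_size=914e6)
        assert round(stats["coverage_pct"], 1) == 87.0

    def test_empty_error(self):
        with pytest.raises(EmptyInputError):
            assembly_stats([])
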