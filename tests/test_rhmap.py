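"""RH mapping: two-point model, grouping, ordering, breaks, bins, summaries."""

import itertools
import math

import numpy as np
import pytest

from wgpmap import simgen
from wgpmap.errors import ContiguityWarning, InvalidParameterError, UndefinedEstimateError
from wgpmap.rhmap import (
    RHGenotypeMatrix,
    assign_deletion_bins,
    centiray,
    collapse_coretained,
    count_obligate_breaks,
    group_markers,
    multipoint_loglik,
    order_loci,
    resolution_summaries,
    two_point,
    two_point_all_pairs,
)


def matrix_from(cols: dict) -> RHGenotypeMatrix:
    names = list(cols)
    data = np.column_stack([np.asarray(cols[m], dtype=float) for m in names])
    return RHGenotypeMatrix([f"l{i}" for i in range(data.shape[0])], names, data)


def _cell_loglik(t, r, n11, n10, n01, n00):
    p11 = r * (1 - t) + r * r * t
    p10 = r * t * (1 - r)
    p00 = (1 - r) * (1 - t) + (1 - r) ** 2 * t
    ll = 0.0
    for n, p in ((n11, p11), (n10 + n01, p10), (n00, p00)):
        if n:
            ll += n * math.log(p) if p > 0 else -math.inf
    return ll


class TestTwoPoint:
    def test_identical_columns_zero_breakage(self):
        col = [1, 0, 1, 1, 0, 0, 1, 0]
        mat = matrix_from({"a": col, "b": col})
        e = two_point("a", "b", mat)
        assert e.theta_hat == 0.0 and e.d_cR == 0.0

    def test_matches_grid_search_oracle(self):
        # counts n11=40, n10=5, n01=5, n00=50
        x = [1] * 45 + [0] * 55
        y = [1] * 40 + [0] * 5 + [1] * 5 + [0] * 50
        mat = matrix_from({"a": x, "b": y})
        e = two_point("a", "b", mat)
        # vectorised grid: theta at 1e-4 steps, r at 1e-3 steps
        t = np.arange(1e-4, 1.0, 1e-4)
        best = (-np.inf, None, None)
        for r in np.arange(0.01, 1.0, 1e-3):
            p11 = r * (1 - t) + r * r * t
            p10 = r * t * (1 - r)
            p00 = (1 - r) * (1 - t) + (1 - r) ** 2 * t
            ll = 40 * np.log(p11) + 10 * np.log(p10) + 50 * np.log(p00)
            k = int(np.argmax(ll))
            if ll[k] > best[0]:
                best = (ll[k], t[k], r)
        _, t_star, r_star = best
        assert e.theta_hat == pytest.approx(t_star, abs=1e-3)
        assert e.r_hat == pytest.approx(r_star, abs=1e-3)
        lod_star = (
            _cell_loglik(t_star, r_star, 40, 5, 5, 50)
            - _cell_loglik(1.0, r_star, 40, 5, 5, 50)
        ) / math.log(10)
        assert e.lod == pytest.approx(lod_star, abs=1e-3)

    def test_independent_markers_rarely_reach_lod_threshold(self):
        rng = np.random.default_rng(12)
        below = 0
        for _ in range(200):
            x = (rng.random(355) < 0.25).astype(float)
            y = (rng.random(355) < 0.25).astype(float)
            e = two_point("a", "b", matrix_from({"a": x, "b": y}))
            below += e.lod < 4.0
        assert below >= 198  # >= 99%

    def test_no_informative_lines_errors(self):
        mat = matrix_from({"a": [np.nan, 1.0], "b": [1.0, np.nan]})
        with pytest.raises(UndefinedEstimateError):
            two_point("a", "b", mat)

    def test_vectorised_pairs_agree_with_scalar(self):
        rng = np.random.default_rng(3)
        data = (rng.random((80, 6)) < 0.3).astype(float)
        mat = RHGenotypeMatrix(
            [f"l{i}" for i in range(80)], [f"m{j}" for j in range(6)], data
        )
        theta, r, lod, n = two_point_all_pairs(mat)
        for i in range(6):
            for j in range(i + 1, 6):
                e = two_point(mat.markers[i], mat.markers[j], mat)
                assert theta[i, j] == pytest.approx(e.theta_hat, abs=1e-5)
                assert lod[i, j] == pytest.approx(e.lod, abs=1e-4)


class TestCentirayMetric:
    def test_shape(self):
        assert centiray(0.0) == 0.0
        grid = np.linspace(0, 0.99, 50)
        vals = [centiray(t) for t in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert centiray(1.0) == math.inf


class TestGrouping:
    def test_mutually_linked_single_group(self):
        rng = np.random.default_rng(1)
        base = (rng.random(200) < 0.3).astype(float)
        cols = {}
        for k in range(4):
            col = base.copy()
            flip = rng.random(200) < 0.05
            col[flip] = 1 - col[flip]
            cols[f"m{k}"] = col
        groups = group_markers(matrix_from(cols))
        assert len(groups) == 1

    def test_two_unlinked_blocks_split(self):
        model = simgen.simulate_chromosome(30_000_000, 15_000_000, 0, seed=2)
        lines = simgen.simulate_rh_panel(model, 300, 6.0, 0.3, seed=2)
        other = simgen.simulate_rh_panel(model, 300, 6.0, 0.3, seed=99)
        posA = {f"a{i}": 2_000_000 + i * 300_000 for i in range(5)}
        posB = {f"b{i}": 2_000_000 + i * 300_000 for i in range(5)}
        callsA = simgen.genotype_calls(lines, posA, seed=2)
        callsB = simgen.genotype_calls(other, posB, seed=3)
        calls = callsA.join(callsB)
        groups = group_markers(RHGenotypeMatrix.from_dataframe(calls))
        assert len(groups) == 2
        assert {frozenset(g) for g in groups} == {
            frozenset(posA), frozenset(posB)
        }

    def test_isolated_marker_own_group(self):
        rng = np.random.default_rng(4)
        base = (rng.random(150) < 0.3).astype(float)
        iso = (rng.random(150) < 0.3).astype(float)
        groups = group_markers(matrix_from({"a": base, "b": base, "c": iso}))
        assert sorted(map(len, groups)) == [1, 2]


class TestCollapse:
    def test_duplicate_columns_merge(self):
        col = [1, 0, 1, 0, 1]
        part, collapsed = collapse_coretained(matrix_from({"a": col, "b": col}))
        assert part == [["a", "b"]] and collapsed.markers == ["a"]

    def test_single_disagreement_keeps_apart(self):
        a = [1, 0, 1, 0, 1]
        b = [1, 0, 1, 0, 0]
        part, _ = collapse_coretained(matrix_from({"a": a, "b": b}))
        assert len(part) == 2

    def test_653_markers_collapse_to_448_loci(self):
        # the marker:locus ratio of the study's map (653 markers, 448 loci)
        model = simgen.simulate_chromosome(200_000_000, 90_000_000, 0, seed=13)
        # heavily fragmented panel and evenly spread loci so every adjacent
        # locus pair is separated by at least one retention change
        lines = simgen.simulate_rh_panel(model, 355, 40.0, 0.25, seed=13)
        rng = np.random.default_rng(13)
        locus_pos = np.linspace(200_000, model.length - 200_000, 448).astype(int)
        marker_pos = {}
        for i in range(448):
            marker_pos[f"M{i:03d}_0"] = int(locus_pos[i])
        extras = rng.integers(0, 448, size=653 - 448)
        for k, i in enumerate(extras):
            marker_pos[f"M{i:03d}_x{k}"] = int(locus_pos[i])
        calls = simgen.genotype_calls(lines, marker_pos, seed=13)
        mat = RHGenotypeMatrix.from_dataframe(calls)
        assert len(mat.markers) == 653
        part, collapsed = collapse_coretained(mat)
        assert len(part) == 448


class TestMultipoint:
    def test_single_locus_chain(self):
        col = [1, 1, 0, 0, 1]
        mat = matrix_from({"a": col})
        r = 0.4
        want = sum(math.log(r) if v == 1 else math.log(1 - r) for v in col)
        assert multipoint_loglik(["a"], mat, [], r) == pytest.approx(want)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(7)
        data = (rng.random((10, 5)) < 0.3).astype(float)
        mat = RHGenotypeMatrix(
            [f"l{i}" for i in range(10)], list("abcde"), data
        )
        thetas = [0.2, 0.5, 0.1, 0.3]
        f = multipoint_loglik(list("abcde"), mat, thetas, 0.3)
        b = multipoint_loglik(list("edcba"), mat, thetas[::-1], 0.3)
        assert f == pytest.approx(b)

    def test_matches_hidden_path_enumeration(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, size=(6, 4)).astype(float)
        calls[0, 1] = np.nan
        calls[3, 2] = np.nan
        mat = RHGenotypeMatrix(
            [f"l{i}" for i in range(6)], list("abcd"), calls
        )
        thetas, r, eps = [0.3, 0.2, 0.4], 0.3, 0.05
        total = 0.0
        for row in mat.calls:
            p = 0.0
            for states in itertools.product([0, 1], repeat=4):
                pr = r if states[0] else 1 - r
                for i, t in enumerate(thetas):
                    s0, s1 = states[i], states[i + 1]
                    pr *= ((1 - t) if s0 == s1 else 0) + t * (r if s1 else 1 - r)
                for i, s in enumerate(states):
                    if not np.isnan(row[i]):
                        pr *= (1 - eps) if int(row[i]) == s else eps
                p += pr
            total += math.log(p)
        got = multipoint_loglik(list("abcd"), mat, thetas, r, epsilon=eps)
        assert got == pytest.approx(total)

    def test_invalid_theta_rejected(self):
        mat = matrix_from({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(InvalidParameterError):
            multipoint_loglik(["a", "b"], mat, [1.5], 0.3)


def _panel_matrix(seed, n_markers, n_lines=355, length=40_000_000, mean_breaks=8.0):
    model = simgen.simulate_chromosome(length, length // 2, 0, seed=seed)
    lines = simgen.simulate_rh_panel(model, n_lines, mean_breaks, 0.25, seed=seed)
    rng = np.random.default_rng(seed + 500)
    pos = {
        f"M{i:03d}": int(p)
        for i, p in enumerate(np.sort(rng.choice(length, n_markers, replace=False)))
    }
    calls = simgen.genotype_calls(lines, pos, seed=seed)
    return RHGenotypeMatrix.from_dataframe(calls), pos


class TestOrderLoci:
    def test_three_loci_best_of_all_orders(self):
        # exhaustive check: the returned order maximises the multipoint
        # likelihood over all distinct 3-locus orders
        mat, pos = _panel_matrix(21, 3)
        _, collapsed = collapse_coretained(mat)
        rh = order_loci(collapsed.markers, collapsed)
        r = collapsed.overall_retention
        theta_all, _, _, _ = two_point_all_pairs(collapsed)
        idx = {m: i for i, m in enumerate(collapsed.markers)}

        def ll(order):
            th = [
                min(max(theta_all[idx[a], idx[b]], 1e-6), 1 - 1e-6)
                for a, b in zip(order, order[1:])
            ]
            return multipoint_loglik(list(order), collapsed, th, r)

        best = max(ll(p) for p in itertools.permutations(collapsed.markers))
        assert ll(rh.locus_names) == pytest.approx(best, abs=1e-6)

    def test_each_locus_appears_once(self):
        mat, _ = _panel_matrix(22, 12)
        _, collapsed = collapse_coretained(mat)
        rh = order_loci(collapsed.markers, collapsed)
        assert sorted(rh.locus_names) == sorted(collapsed.markers)

    def test_canonical_orientation(self):
        mat, _ = _panel_matrix(23, 8)
        _, collapsed = collapse_coretained(mat)
        rh = order_loci(collapsed.markers, collapsed)
        assert rh.locus_names[0] < rh.locus_names[-1]

    def test_positions_nondecreasing_from_zero(self):
        mat, _ = _panel_matrix(24, 10)
        _, collapsed = collapse_coretained(mat)
        rh = order_loci(collapsed.markers, collapsed)
        assert rh.positions_cR[0] == 0.0
        assert np.all(np.diff(rh.positions_cR) >= 0)

    def test_search_reaches_truth_likelihood(self):
        # search adequacy: the chosen order is at least as likely as the truth
        for seed in (31, 32, 33):
            mat, pos = _panel_matrix(seed, 15)
            _, collapsed = collapse_coretained(mat)
            rh = order_loci(collapsed.markers, collapsed)
            truth = sorted(collapsed.markers, key=lambda m: pos[m])
            r = collapsed.overall_retention
            theta_all, _, _, _ = two_point_all_pairs(collapsed)
            idx = {m: i for i, m in enumerate(collapsed.markers)}

            def ll(order):
                th = [
                    min(max(theta_all[idx[a], idx[b]], 1e-6), 1 - 1e-6)
                    for a, b in zip(order, order[1:])
                ]
                return multipoint_loglik(order, collapsed, th, r)

            assert ll(rh.locus_names) >= ll(truth) - 1e-6


class TestObligateBreaks:
    def test_constant_line_no_breaks(self):
        mat = matrix_from({"a": [1], "b": [1], "c": [1], "d": [1]})
        assert count_obligate_breaks(list("abcd"), mat) == 0

    def test_alternating_line(self):
        mat = matrix_from({"a": [1], "b": [0], "c": [1], "d": [0]})
        assert count_obligate_breaks(list("abcd"), mat) == 3

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(17)
        data = rng.integers(0, 2, size=(6, 6)).astype(float)
        data[2, 3] = np.nan
        mat = RHGenotypeMatrix(
            [f"l{i}" for i in range(6)], list("abcdef"), data
        )
        order = list("abcdef")
        direct = 0
        for row in data:
            vals = [v for v in row if not np.isnan(v)]
            direct += sum(1 for x, y in zip(vals, vals[1:]) if x != y)
        assert count_obligate_breaks(order, mat) == direct

    def test_true_order_minimises_breaks(self):
        mat, pos = _panel_matrix(41, 20)
        truth = sorted(mat.markers, key=lambda m: pos[m])
        base = count_obligate_breaks(truth, mat)
        rng = np.random.default_rng(41)
        for _ in range(100):
            perm = list(rng.permutation(truth))
            assert count_obligate_breaks(perm, mat) >= base


class TestDeletionBins:
    def test_single_line_at_most_two_bins(self):
        dels = matrix_from({"a": [1], "b": [1], "c": [0], "d": [0]})
        bins = assign_deletion_bins(list("abcd"), dels)
        assert len(bins) <= 2

    def test_everything_retained_single_bin(self):
        dels = matrix_from({m: [1, 1, 1] for m in "abcd"}.copy())
        data = np.ones((3, 4))
        mat = RHGenotypeMatrix(["l0", "l1", "l2"], list("abcd"), data)
        bins = assign_deletion_bins(list("abcd"), mat)
        assert len(bins) == 1

    def test_noncontiguous_pattern_warns(self):
        mat = matrix_from({"a": [1], "b": [0], "c": [1]})
        with pytest.warns(ContiguityWarning):
            assign_deletion_bins(list("abc"), mat)

    def test_18_breakpoints_plus_centromere_split_give_20_bins(self):
        model = simgen.simulate_chromosome(40_000_000, 18_000_000, 0, seed=5)
        dels = simgen.simulate_deletion_lines(model, seed=5)
        # markers guaranteed in every breakpoint-delimited segment
        bps = sorted(
            {s if s > 0 else e for ln in dels for s, e in ln.retained_intervals}
        )
        # one marker per breakpoint-delimited segment, with the segment that
        # spans the centromere probed on both sides (arm-specific libraries)
        bounds = sorted({0, *bps, model.arm_boundary, model.length})
        pos = {}
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            pos[f"M{i:02d}"] = (lo + hi) // 2
        calls = simgen.genotype_calls(dels, pos, seed=5)
        mat = RHGenotypeMatrix.from_dataframe(calls)
        order = sorted(pos, key=lambda m: pos[m])
        arms = {m: model.arm_of(pos[m]) for m in order}
        bins = assign_deletion_bins(order, mat, arm_of_locus=arms)
        assert len(bins) == 20
        n_s = sum(1 for b in bins if b.pattern[0] == "S")
        assert (n_s, len(bins) - n_s) == (7, 13)


class TestMapSummaries:
    def test_study_scale_resolution_values(self):
        out = resolution_summaries(
            total_cR=1560.7, n_loci=448, mapped_mb=794.8, obligate_breaks=1277
        )
        assert round(out["cR_per_locus"], 1) == 3.5
        assert round(out["kb_per_cR"]) == 509
        assert round(out["mb_per_break"], 2) == 0.62
        assert round(out["kb_per_break"]) == 622

    def test_bin_resolution(self):
        out = resolution_summaries(100.0, 10, 84.3, 180)
        assert round(out["mb_per_break"], 2) == 0.47

    def test_zero_breaks_undefined_not_infinite(self):
        out = resolution_summaries(100.0, 10, 50.0, 0)
        assert out["mb_per_break"] is None


def test_retention_recovered_within_tolerance():
    # estimated retention within +/-0.03 of the simulated value at 355 lines
    mat, _ = _panel_matrix(51, 60)
    _, collapsed = collapse_coretained(mat)
    rh = order_loci(collapsed.markers, collapsed)
    assert abs(rh.r_hat - 0.25) < 0.03
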