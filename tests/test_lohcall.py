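"""LOH tract calling, merging, classification, breakpoints and corrections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lohdrive import (HET, HOM_P1, HOM_P2, MISSING, CorrectionModel, LOHEvent,
                      LOHTract, MarkerMap, call_clone_events, call_tracts,
                      classify_event, correct_counts, estimate_breakpoint,
                      events_to_frame, merge_tracts)

H, P1, P2, M = HET, HOM_P1, HOM_P2, MISSING


def brute_force_tracts(calls, positions, length, missing="transparent"):
    """Independent enumeration of runs and midpoint boundaries."""
    if missing == "transparent":
        informative = [i for i, c in enumerate(calls) if c != M]
    else:
        informative = list(range(len(calls)))
    runs, cur = [], []
    for i in informative:
        c = calls[i]
        if c in (P1, P2):
            if cur and calls[cur[-1]] != c:
                runs.append(cur)
                cur = []
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
                cur = []
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        prev = [j for j in informative if j < run[0]]
        nxt = [j for j in informative if j > run[-1]]
        left = 1.0 if not prev else (positions[prev[-1]] + positions[run[0]]) / 2
        right = float(length) if not nxt else (positions[run[-1]] + positions[nxt[0]]) / 2
        out.append((calls[run[0]], tuple(run), left, right))
    return out


def _tract_map(n, length=2000):
    """A map whose first n marker slots are free for crafted call vectors."""
    pos = np.linspace(100, 1000, n).astype(int) if n > 1 else np.array([100, 900])
    return MarkerMap([("c", length)], {"c": (1500, 1510)}, {"c": pos})


class TestCallTracts:
    def test_midpoint_boundaries(self):
        # markers 100..500 step 100, calls H,H,P1,P1,H -> one tract [250, 450]
        mp = MarkerMap([("c", 1000)], {"c": (600, 610)},
                       {"c": np.array([100, 200, 300, 400, 500])})
        tracts = call_tracts(np.array([H, H, P1, P1, H]), mp, "c")
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.homolog, t.left, t.right, t.n_markers) == ("P1", 250, 450, 2)

    def test_all_het_is_empty(self, toy_map):
        assert call_tracts(np.array([H] * 5), toy_map, "chrA") == []

    def test_alternating_homologs_split(self):
        mp = _tract_map(5)
        tracts = call_tracts(np.array([H, P1, H, P2, H]), mp, "c")
        assert [(t.homolog, t.n_markers) for t in tracts] == [("P1", 1), ("P2", 1)]

    def test_chromosome_end_boundaries(self):
        mp = MarkerMap([("c", 1000)], {"c": (600, 610)},
                       {"c": np.array([100, 200, 300, 400, 500])})
        tracts = call_tracts(np.array([P2, P2, H, H, P2]), mp, "c")
        assert tracts[0].left == 1 and tracts[0].right == 250
        assert tracts[1].left == 450 and tracts[1].right == 1000

    def test_missing_transparent_bridges_run(self):
        mp = _tract_map(5)
        tracts = call_tracts(np.array([H, P1, M, P1, H]), mp, "c")
        assert len(tracts) == 1
        assert tracts[0].n_markers == 2                    # MISSING not counted
        assert list(tracts[0].marker_indices) == [1, 3]

    def test_missing_break_splits_run(self):
        mp = _tract_map(5)
        tracts = call_tracts(np.array([H, P1, M, P1, H]), mp, "c", missing="break")
        assert len(tracts) == 2

    def test_unknown_call_value_raises(self):
        mp = _tract_map(3)
        with pytest.raises(ValueError, match="unknown call"):
            call_tracts(np.array([H, 7, H]), mp, "c")

    @settings(max_examples=200, deadline=None)
    @given(
        calls=st.lists(st.sampled_from([H, P1, P2, M]), min_size=2, max_size=12),
        data=st.data(),
        mode=st.sampled_from(["transparent", "break"]),
    )
    def test_matches_brute_force_enumeration(self, calls, data, mode):
        n = len(calls)
        positions = data.draw(
            st.lists(st.integers(1, 1000), min_size=n, max_size=n, unique=True)
            .map(sorted))
        mp = MarkerMap([("c", 2000)], {"c": (1500, 1510)},
                       {"c": np.array(positions)})
        got = call_tracts(np.array(calls), mp, "c", missing=mode)
        expected = brute_force_tracts(calls, positions, 2000, missing=mode)
        assert len(got) == len(expected)
        for t, (hom, run, left, right) in zip(got, expected):
            assert {"P1": P1, "P2": P2}[t.homolog] == hom
            assert tuple(t.marker_indices) == run
            assert (t.left, t.right) == (left, right)


def _tract(left, right, homolog="P1", chrom="c", clone="x", idx=(0,)):
    return LOHTract(clone, chrom, homolog, idx[0], idx[-1], left, right,
                    np.array(idx))


class TestMergeTracts:
    def test_gap_below_threshold_merges(self):
        events = merge_tracts([_tract(100, 20_000), _tract(29_999, 40_000, idx=(1,))])
        assert len(events) == 1
        assert (events[0].left, events[0].right) == (100, 40_000)

    def test_gap_at_threshold_stays_split(self):
        events = merge_tracts([_tract(100, 20_000), _tract(30_000, 40_000, idx=(1,))])
        assert len(events) == 2

    def test_single_tract_identity(self):
        t = _tract(100, 500)
        (event,) = merge_tracts([t])
        assert (event.left, event.right, event.homolog) == (t.left, t.right, t.homolog)
        assert event.n_markers == t.n_markers

    def test_homolog_switch_never_merges(self):
        events = merge_tracts([
            _tract(100, 2_000, "P1"),
            _tract(3_000, 4_000, "P2", idx=(1,)),
            _tract(5_000, 6_000, "P1", idx=(2,)),
        ])
        assert len(events) == 3

    def test_transitive_chain(self):
        events = merge_tracts([
            _tract(100, 2_000, idx=(0,)),
            _tract(5_000, 8_000, idx=(1,)),
            _tract(12_000, 15_000, idx=(2,)),
        ])
        assert len(events) == 1 and events[0].n_markers == 3

    def test_idempotent_and_order_independent(self):
        tracts = [_tract(100, 2_000, idx=(0,)), _tract(5_000, 8_000, idx=(1,)),
                  _tract(40_000, 45_000, idx=(2,))]
        forward = merge_tracts(tracts)
        reverse = merge_tracts(tracts[::-1])
        assert [(e.left, e.right) for e in forward] == [(e.left, e.right) for e in reverse]
        again = merge_tracts([t for e in forward for t in e.tracts])
        assert [(e.left, e.right) for e in again] == [(e.left, e.right) for e in forward]

    def test_different_clones_never_merge(self):
        events = merge_tracts([_tract(100, 2_000, clone="a"),
                               _tract(3_000, 4_000, clone="b")])
        assert len(events) == 2


class TestClassifyAndBreakpoint:
    def _event_from_calls(self, toy_map, calls):
        tracts = call_tracts(np.array(calls), toy_map, "chrA")
        (event,) = merge_tracts(tracts)
        return event

    def test_rightmost_marker_is_terminal(self, toy_map):
        ev = self._event_from_calls(toy_map, [H, H, H, P1, P1])
        assert classify_event(ev, toy_map) == "terminal"
        assert not ev.possible_aneuploidy

    def test_leftmost_marker_is_terminal(self, toy_map):
        ev = self._event_from_calls(toy_map, [P2, H, H, H, H])
        assert classify_event(ev, toy_map) == "terminal"

    def test_mid_arm_is_interstitial(self, toy_map):
        ev = self._event_from_calls(toy_map, [H, H, P1, P1, H])
        assert classify_event(ev, toy_map) == "interstitial"

    def test_whole_chromosome_flagged(self, toy_map):
        ev = self._event_from_calls(toy_map, [P1] * 5)
        assert classify_event(ev, toy_map) == "terminal"
        assert ev.possible_aneuploidy

    def test_interstitial_breakpoint_is_midpoint(self, toy_map):
        ev = LOHEvent("x", "chrA", "P1", 1_000, 2_000, [], np.array([2]),
                      kind="interstitial")
        assert estimate_breakpoint(ev, toy_map) == 1_500

    def test_long_right_arm_terminal_offset(self):
        mp = MarkerMap([("c", 400_000)], {"c": (50_000, 50_100)},
                       {"c": np.array([10_000, 100_000, 200_000, 300_000])})
        ev = LOHEvent("x", "c", "P1", 100_000, 300_000, [], np.array([1, 2, 3]),
                      kind="terminal")
        assert estimate_breakpoint(ev, mp) == 110_000

    def test_long_left_arm_terminal_offset(self):
        mp = MarkerMap([("c", 400_000)], {"c": (50_000, 50_100)},
                       {"c": np.array([1_000, 10_000, 30_000, 100_000])})
        ev = LOHEvent("x", "c", "P1", 1.0, 30_500, [], np.array([0, 1, 2]),
                      kind="terminal")
        assert estimate_breakpoint(ev, mp) == 20_500

    def test_short_terminal_uses_midpoint(self):
        mp = MarkerMap([("c", 400_000)], {"c": (50_000, 50_100)},
                       {"c": np.array([10_000, 100_000, 390_000, 395_000])})
        ev = LOHEvent("x", "c", "P1", 385_000, 400_000, [], np.array([2, 3]),
                      kind="terminal")
        assert estimate_breakpoint(ev, mp) == 392_500


class TestCorrectCounts:
    def test_long_events_barely_corrected(self, toy_map):
        events = [LOHEvent("x", "chrA", "P1", 1, 100_000, [], np.array([0]),
                           kind="terminal")]
        model = CorrectionModel(iloh_median_bp=None, mean_spacing=320)
        corrected = correct_counts(events, toy_map, model)
        assert corrected["x"] == pytest.approx(1.0, rel=1e-6)

    def test_detection_probability_closed_form(self):
        model = CorrectionModel(iloh_median_bp=None)
        assert model.p_detect(320.0, 320.0) == pytest.approx(1 - np.exp(-1))

    def test_detection_probability_matches_placement_oracle(self):
        # place events of length = mean spacing on exponential-gap markers
        rng = np.random.default_rng(5)
        s, ell, n = 320.0, 320.0, 40_000
        gaps = rng.exponential(s, 400_000)
        pos = np.cumsum(gaps)
        starts = rng.uniform(0, pos[-1] - ell, size=n)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, starts + ell)
        covered = (hi > lo).mean()
        model = CorrectionModel(iloh_median_bp=None)
        assert model.p_detect(ell, s) == pytest.approx(covered, abs=3 * 0.5 / np.sqrt(n))

    def test_corrected_total_within_ten_percent_of_truth(self, genome_map, genome_cohort):
        from lohdrive import call_events
        gm, truth, _ = genome_cohort
        events = call_events(gm)
        corrected = correct_counts(events, genome_map, clones=gm.clones)
        detected = events_to_frame(events).groupby("clone").size()
        true_total = sum(
            1 for ct in truth.values() for e in ct.events if e.end - e.start + 1 >= 17
        )
        assert corrected.sum() >= detected.sum()
        assert abs(corrected.sum() - true_total) / true_total < 0.10

    def test_monotone_in_length(self):
        model = CorrectionModel(iloh_median_bp=None)
        lengths = [10, 50, 320, 5_000, 100_000]
        ps = [model.p_detect(l, 320.0) for l in lengths]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert 0 < ps[0] and ps[-1] <= 1


class TestCallerOracle:
    """Caller vs simulator ground truth on a genome-scale cohort."""

    ISOLATION_BP = 30_000

    def test_isolated_true_events_recovered_exactly(self, genome_map, genome_cohort):
        gm, truth, _ = genome_cohort
        checked = 0
        for clone in gm.clones:
            events = call_clone_events(gm, clone)
            called_by_chrom = {}
            for e in events:
                called_by_chrom.setdefault(e.chrom, []).append(e)
            for te in truth[clone].events:
                if len(te.footprint) == 0:
                    continue
                # isolation: no other true event interval within 30 kb
                near = [
                    o for o in truth[clone].events
                    if o is not te and o.chrom == te.chrom
                    and not (o.start > te.end + self.ISOLATION_BP
                             or o.end < te.start - self.ISOLATION_BP)
                ]
                if near:
                    continue
                matches = [
                    c for c in called_by_chrom.get(te.chrom, [])
                    if set(c.marker_indices.tolist()) == set(te.footprint.tolist())
                ]
                assert len(matches) == 1, (clone, te.chrom, te.start, te.end)
                call = matches[0]
                assert call.homolog == te.homolog
                # independent expected class: does the footprint touch an arm end?
                pos = genome_map.positions(te.chrom)
                l_lo, l_hi = genome_map.arm_marker_span(te.chrom, "L")
                r_lo, r_hi = genome_map.arm_marker_span(te.chrom, "R")
                fp = set(te.footprint.tolist())
                expected_terminal = (l_hi > l_lo and l_lo in fp) or \
                                    (r_hi > r_lo and (r_hi - 1) in fp)
                assert call.kind == ("terminal" if expected_terminal else "interstitial")
                checked += 1
        assert checked > 1_000   # the oracle exercised a large event sample

    def test_no_spurious_calls(self, genome_cohort):
        gm, truth, _ = genome_cohort
        for clone in gm.clones[:40]:
            events = call_clone_events(gm, clone)
            called = {
                (e.chrom, int(i)) for e in events for i in e.marker_indices
            }
            true_fp = {
                (e.chrom, int(i)) for e in truth[clone].events for i in e.footprint
            }
            assert called == true_fp
            assert all(e.n_markers >= 1 for e in events)
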