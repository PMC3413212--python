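"""Candidate enumeration, scoring and trace assembly."""

import numpy as np
import pytest

from rnatrace.tracing import (
    Candidate,
    Trace,
    TraceAnchor,
    auto_trace,
    combine_scores,
    enumerate_candidates,
    extend_trace,
    rank_candidates,
    score_candidate,
)


class TestTraceContainer:
    def test_direction_fixed_and_gap_bound_enforced(self):
        with pytest.raises(ValueError):
            Trace(direction="sideways", anchors=(TraceAnchor(phosphate=np.zeros(3)),))
        with pytest.raises(ValueError):
            Trace(
                direction="5to3",
                anchors=(
                    TraceAnchor(phosphate=np.zeros(3)),
                    TraceAnchor(phosphate=np.array([11.0, 0, 0])),
                ),
            )

    def test_sequence_order_reverses_for_3to5(self):
        anchors = (
            TraceAnchor(phosphate=np.array([0.0, 0, 0])),
            TraceAnchor(phosphate=np.array([6.0, 0, 0])),
        )
        tr = Trace(direction="3to5", anchors=anchors)
        ordered = tr.anchors_in_sequence_order()
        assert np.allclose(ordered[0].phosphate, [6.0, 0, 0])


class TestEnumeration:
    def test_counts_and_radius_bound(self, helix7):
        _, model, grid, peaks = helix7
        tr = Trace.start(model.atom(0, "P"))
        cands = enumerate_candidates(tr, peaks, grid)
        # the true next phosphate is among the candidates
        best = min(
            np.linalg.norm(c.p_candidate - model.atom(1, "P")) for c in cands
        )
        assert best <= 1.0
        for c in cands:
            assert np.linalg.norm(c.p_candidate - model.atom(0, "P")) <= 10.0 + 1e-9

    def test_far_start_yields_empty_list(self, helix7):
        _, model, grid, peaks = helix7
        tr = Trace.start(model.atom(0, "P") - np.array([50.0, 0, 0]))
        assert enumerate_candidates(tr, peaks, grid) == []

    def test_used_peaks_excluded(self, helix7, curves):
        _, model, grid, peaks = helix7
        tr = Trace.start(model.atom(0, "P"))
        cands = rank_candidates(
            [score_candidate(c, tr, curves, grid=grid) for c in enumerate_candidates(tr, peaks, grid)]
        )
        tr2 = extend_trace(tr, cands, 0)
        taken = tr2.anchors[-1].phosphate
        for c in enumerate_candidates(tr2, peaks, grid):
            assert np.linalg.norm(c.p_candidate - taken) > 0.4


class TestScoring:
    def test_sum_rule_matches_hand_computation(self):
        comps = {"s_dist": 0.2, "s_angle_p": 0.1, "s_angle_s": 0.1, "s_density": 0.3}
        weights = {"s_dist": 5.0, "s_angle_p": 1.0, "s_angle_s": 1.0, "s_density": 15.0}
        assert combine_scores(comps, weights, "sum") == pytest.approx(5.7, abs=1e-12)

    @pytest.mark.parametrize("rule", ["sum", "logsum"])
    def test_monotone_in_each_component(self, rule):
        comps = {"s_dist": 0.4, "s_angle_p": 0.5, "s_angle_s": 0.6, "s_density": 1.2}
        weights = {"s_dist": 5.0, "s_angle_p": 1.0, "s_angle_s": 1.0, "s_density": 15.0}
        base = combine_scores(comps, weights, rule)
        for key in comps:
            bumped = dict(comps)
            bumped[key] += 0.1
            assert combine_scores(bumped, weights, rule) >= base

    def test_symmetric_candidates_tie(self, curves):
        from rnatrace.density import DensityGrid

        n = 33
        ax = np.linspace(-8, 8, n)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = np.exp(-(X**2 + Y**2 + Z**2) / 30.0)
        grid = DensityGrid(origin=np.full(3, -8.0), voxel_spacing=np.full(3, ax[1] - ax[0]), values=vals)
        tr = Trace.start(np.array([0.0, 0.0, 0.0]))
        from rnatrace.geometry import place_c1prime, place_sugar_center, PhosphatePair

        out = []
        for p in (np.array([5.8, 0, 0]), np.array([-5.8, 0, 0])):  # mirror pair
            pair = PhosphatePair(p5=tr.current.phosphate, p3=p)
            sugar = place_sugar_center(pair, grid)
            cand = Candidate(p_candidate=p, sugar=sugar, c1p=place_c1prime(sugar, pair))
            out.append(score_candidate(cand, tr, curves, grid=grid))
        assert out[0].s_overall == pytest.approx(out[1].s_overall, abs=1e-6)

    def test_first_step_has_no_angle_terms(self, helix7, curves):
        _, model, grid, peaks = helix7
        tr = Trace.start(model.atom(0, "P"))
        c = enumerate_candidates(tr, peaks, grid)[0]
        scored = score_candidate(c, tr, curves, grid=grid)
        assert set(scored.component_scores) == {"s_dist", "s_density"}


class TestExtension:
    def test_pick_zero_takes_top_ranked(self, helix7, curves):
        _, model, grid, peaks = helix7
        tr = Trace.start(model.atom(0, "P"))
        cands = rank_candidates(
            [score_candidate(c, tr, curves, grid=grid) for c in enumerate_candidates(tr, peaks, grid)]
        )
        tr2 = extend_trace(tr, cands, 0)
        assert np.allclose(tr2.anchors[-1].phosphate, cands[0].p_candidate)
        # 5'->3': the completed nucleotide's C1' attaches to the old end
        assert tr2.anchors[0].c1p is not None

    def test_out_of_range_pick_rejected(self, helix7, curves):
        _, model, grid, peaks = helix7
        tr = Trace.start(model.atom(0, "P"))
        cands = [score_candidate(c, tr, curves, grid=grid) for c in enumerate_candidates(tr, peaks, grid)]
        with pytest.raises(IndexError):
            extend_trace(tr, cands, len(cands))


class TestAutoTrace:
    def test_clean_helix_fully_recovered(self, helix7, traced7):
        _, model, _, _ = helix7
        trace, report = traced7
        assert len(trace.anchors) == 7
        tp = trace.phosphates()
        for i in range(7):
            assert np.linalg.norm(tp[i] - model.atom(i, "P")) <= 1.0
        assert all(s["status"] == "ok" for s in report)

    def test_mixed_conformer_seven_mer_recovers_six_of_seven(self, mixed7, curves):
        spec, model, grid, peaks = mixed7
        trace, _ = auto_trace(
            grid, peaks, start=model.atom(0, "P"), length=7, curves=curves,
            sequence=spec.sequence,
        )
        tp = trace.phosphates()
        hits = sum(
            np.linalg.norm(tp[i] - model.atom(i, "P")) <= 1.0
            for i in range(min(len(tp), 7))
        )
        assert hits >= 6

    def test_direction_reversal_recovers_same_phosphates(self, helix7, curves):
        _, model, grid, peaks = helix7
        fwd, _ = auto_trace(grid, peaks, start=model.atom(0, "P"), length=7,
                            curves=curves, place_bases=False)
        rev, _ = auto_trace(grid, peaks, start=model.atom(6, "P"), length=7,
                            curves=curves, direction="3to5", place_bases=False)
        a = fwd.phosphates()
        b = np.array([x.phosphate for x in rev.anchors_in_sequence_order()])
        assert a.shape == b.shape
        assert np.allclose(np.sort(a, axis=0), np.sort(b, axis=0), atol=1e-9)

    def test_deterministic_given_same_inputs(self, helix7, curves):
        _, model, grid, peaks = helix7
        t1, r1 = auto_trace(grid, peaks, start=model.atom(0, "P"), length=4,
                            curves=curves, place_bases=False)
        t2, r2 = auto_trace(grid, peaks, start=model.atom(0, "P"), length=4,
                            curves=curves, place_bases=False)
        assert np.allclose(t1.phosphates(), t2.phosphates())
        assert r1 == r2
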