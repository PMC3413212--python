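"""Backbone tracing: enumerate, score and accept next-nucleotide candidates.

Starting from a seed phosphate peak, every peak within 10 Å of the current
chain end is a candidate next phosphate.  For each candidate the geometry
module proposes a sugar center and C1' atom, and the candidate is scored

    s_overall = w_dist*s_dist + w_angle_p*s_angle_p
              + w_angle_s*s_angle_s + w_density*s_density

with likelihood terms from the reference curves and s_density summing map
values along the G->P5' and G->P3' segments plus the sugar center and the
candidate phosphate itself.  The first step of a chain has no angle history
and uses the reduced form  w'_dist*s_dist + w'_density*s_density.
Candidates are ranked by s_overall; batch tracing takes the top candidate
at every step (individual steps can be overridden).  A trace runs either
5'->3' or 3'->5'; the direction is fixed at the start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .bases import PlacedBase, fit_base, mutate_base, place_base_vector, refine_orientation
from .density import DensityGrid, PeakSet, peaks_near, sample_segment_density
from .geometry import (
    MAX_PP_DISTANCE,
    PhosphatePair,
    RegressionCoefficients,
    SugarCenter,
    angle,
    place_c1prime,
    place_sugar_center,
)
from .likelihoods import ReferenceCurves

log = logging.getLogger(__name__)

__all__ = [
    "ScoreWeights",
    "Candidate",
    "TraceAnchor",
    "Trace",
    "enumerate_candidates",
    "score_candidate",
    "extend_trace",
    "auto_trace",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Empirical scoring weights; the wp_* pair is the first-nucleotide
    variant used when no angle history exists yet.

    The weights assume commensurable terms: likelihoods are evaluated in
    likelihood-ratio units ([0, 1], value over curve maximum) and
    s_density is the mean sigma level per sample point (divided by
    ``density_ref``).  Density then dominates the score — phosphates are
    the strongest features in the map — while the geometry terms break
    near-ties between comparably dense paths.
    """

    w_dist: float = 5.0
    w_angle_p: float = 1.0
    w_angle_s: float = 1.0
    w_density: float = 15.0
    wp_dist: float = 1.0
    wp_density: float = 10.0
    density_ref: float = 1.0  # sigma units per sample point
    #: "logsum" scores a candidate by the weighted product of its terms
    #: (sum of weighted logs): a geometrically absurd candidate is vetoed
    #: by its near-zero likelihood no matter how dense its path.  "sum" is
    #: the plain weighted sum.
    combine: str = "logsum"


@dataclass(frozen=True)
class TraceAnchor:
    """Per-nucleotide anchors accumulated during tracing."""

    phosphate: np.ndarray
    c1p: np.ndarray | None = None
    sugar: SugarCenter | None = None
    base: PlacedBase | None = None


@dataclass(frozen=True)
class Candidate:
    p_candidate: np.ndarray
    sugar: SugarCenter
    c1p: np.ndarray
    component_scores: dict[str, float] = field(default_factory=dict)
    s_overall: float = 0.0
    base: PlacedBase | None = None


@dataclass(frozen=True)
class Trace:
    """An ordered backbone trace.  ``anchors`` is kept in build order; for
    3'->5' traces the sequence order is the reverse."""

    direction: str  # "5to3" | "3to5"
    anchors: tuple[TraceAnchor, ...]

    def __post_init__(self):
        if self.direction not in ("5to3", "3to5"):
            raise ValueError("direction must be '5to3' or '3to5'")
        if len(self.anchors) < 1:
            raise ValueError("a trace needs at least one anchor")
        ps = self.phosphates()
        gaps = np.linalg.norm(np.diff(ps, axis=0), axis=1)
        if np.any(gaps > MAX_PP_DISTANCE + 1e-9):
            raise ValueError("consecutive trace phosphates exceed 10 Å")

    def phosphates(self) -> np.ndarray:
        return np.array([a.phosphate for a in self.anchors])

    def anchors_in_sequence_order(self) -> tuple[TraceAnchor, ...]:
        return self.anchors if self.direction == "5to3" else tuple(reversed(self.anchors))

    @property
    def current(self) -> TraceAnchor:
        return self.anchors[-1]

    @classmethod
    def start(cls, phosphate, direction: str = "5to3") -> "Trace":
        return cls(direction=direction, anchors=(TraceAnchor(phosphate=np.asarray(phosphate, dtype=float)),))


def _pair_for(trace: Trace, candidate_p: np.ndarray) -> PhosphatePair:
    cur = trace.current.phosphate
    if trace.direction == "5to3":
        return PhosphatePair(p5=cur, p3=candidate_p)
    return PhosphatePair(p5=candidate_p, p3=cur)


def enumerate_candidates(
    trace: Trace,
    peaks: PeakSet,
    grid: DensityGrid,
    coeffs: RegressionCoefficients | None = None,
    radius: float = MAX_PP_DISTANCE,
    exclude_radius: float = 0.5,
) -> list[Candidate]:
    """Build an unscored candidate per peak within ``radius`` of the chain
    end.  Peaks already claimed by the trace are excluded (prevents
    immediate backtracking).  Empty result means the trace is stuck."""
    cur = trace.current.phosphate
    used = trace.phosphates()
    out = []
    for peak in peaks_near(peaks, cur, radius):
        if np.linalg.norm(peak.position - cur) < 1e-9:
            continue
        if np.min(np.linalg.norm(used - peak.position, axis=1)) < exclude_radius:
            continue
        pair = _pair_for(trace, peak.position)
        sugar = place_sugar_center(pair, grid, coeffs)
        c1p = place_c1prime(sugar, pair, coeffs)
        out.append(Candidate(p_candidate=peak.position, sugar=sugar, c1p=c1p))
    if not out:
        log.info("trace stuck: no candidate peaks within %.1f Å", radius)
    return out


def score_candidate(
    cand: Candidate,
    trace: Trace,
    curves: ReferenceCurves,
    weights: ScoreWeights | None = None,
    grid: DensityGrid | None = None,
    n_samples: int = 10,
) -> Candidate:
    """Attach component scores and s_overall to a candidate."""
    weights = weights or ScoreWeights()
    cur = trace.current
    d = float(np.linalg.norm(cand.p_candidate - cur.phosphate))
    s_dist = float(curves.dist.eval_ratio(d))
    g = cand.sugar.position
    pair = _pair_for(trace, cand.p_candidate)
    raw_density = (
        sample_segment_density(grid, g, pair.p5, n_samples)
        + sample_segment_density(grid, g, pair.p3, n_samples)
        + float(grid.sample(g))
        + float(grid.sample(cand.p_candidate))
    )
    s_density = raw_density / ((2 * n_samples + 2) * weights.density_ref)
    comps = {"s_dist": s_dist, "s_density": s_density}

    first = len(trace.anchors) < 2
    if first:
        terms = {"s_dist": weights.wp_dist, "s_density": weights.wp_density}
    else:
        prev = trace.anchors[-2]
        # previous C1', the shared phosphate, candidate C1'
        c1_prev = prev.c1p if trace.direction == "5to3" else cur.c1p
        if c1_prev is None:
            raise ValueError("angle terms need a C1' anchor on the previous nucleotide")
        s_angle_p = float(
            curves.angle_p.eval_ratio(angle(prev.phosphate, cur.phosphate, cand.p_candidate))
        )
        s_angle_s = float(curves.angle_s.eval_ratio(angle(c1_prev, cur.phosphate, cand.c1p)))
        comps.update({"s_angle_p": s_angle_p, "s_angle_s": s_angle_s})
        terms = {
            "s_dist": weights.w_dist,
            "s_angle_p": weights.w_angle_p,
            "s_angle_s": weights.w_angle_s,
            "s_density": weights.w_density,
        }
    s = combine_scores(comps, terms, weights.combine)
    return replace(cand, component_scores=comps, s_overall=s)


def combine_scores(components: dict[str, float], term_weights: dict[str, float], rule: str = "logsum") -> float:
    """Combine component scores into s_overall under the chosen rule."""
    if rule == "logsum":
        return float(
            sum(w * np.log(max(components[k], 1e-12)) for k, w in term_weights.items())
        )
    if rule == "sum":
        return float(sum(w * components[k] for k, w in term_weights.items()))
    raise ValueError(f"unknown combination rule {rule!r}")


def rank_candidates(cands: list[Candidate]) -> list[Candidate]:
    return sorted(cands, key=lambda c: -c.s_overall)


def extend_trace(trace: Trace, candidates: list[Candidate], pick: int = 0) -> Trace:
    """Accept a candidate (by rank index) and grow the trace.

    The sugar/C1'/base of the accepted candidate belong to the nucleotide
    between the old chain end and the new phosphate: tracing 5'->3' they
    attach to the old end (its base and sugar lie ahead of its phosphate);
    tracing 3'->5' they attach to the new anchor.
    """
    if not 0 <= pick < len(candidates):
        raise IndexError(f"pick {pick} out of range ({len(candidates)} candidates)")
    cand = candidates[pick]
    anchors = list(trace.anchors)
    if trace.direction == "5to3":
        anchors[-1] = replace(
            anchors[-1], c1p=cand.c1p, sugar=cand.sugar, base=cand.base
        )
        anchors.append(TraceAnchor(phosphate=cand.p_candidate))
    else:
        anchors.append(
            TraceAnchor(
                phosphate=cand.p_candidate, c1p=cand.c1p, sugar=cand.sugar, base=cand.base
            )
        )
    return Trace(direction=trace.direction, anchors=tuple(anchors))


def auto_trace(
    grid: DensityGrid,
    peaks: PeakSet,
    start,
    length: int,
    curves: ReferenceCurves,
    direction: str = "5to3",
    sequence: str | None = None,
    weights: ScoreWeights | None = None,
    coeffs: RegressionCoefficients | None = None,
    picks: dict[int, int] | None = None,
    place_bases: bool = True,
    w_chi: float = 1.0,
) -> tuple[Trace, list[dict]]:
    """Batch trace: seed at the peak closest to ``start`` and repeatedly
    accept the top-ranked candidate (or a per-step override from ``picks``)
    until ``length`` phosphates are placed or the trace is stuck.

    Returns the trace and a per-step report (candidate rankings with
    component scores).
    """
    near = peaks_near(peaks, np.asarray(start, dtype=float), radius=10.0)
    if not near:
        raise ValueError("no peak within 10 Å of the start point")
    trace = Trace.start(near[0].position, direction=direction)
    picks = picks or {}
    report: list[dict] = []
    step = 0
    while len(trace.anchors) < length:
        cands = enumerate_candidates(trace, peaks, grid, coeffs)
        if not cands:
            report.append({"step": step, "status": "stuck", "candidates": []})
            break
        cands = rank_candidates(
            [score_candidate(c, trace, curves, weights, grid) for c in cands]
        )
        pick = picks.get(step, 0)
        pick = min(pick, len(cands) - 1)
        if place_bases:
            chosen = cands[pick]
            pair = _pair_for(trace, chosen.p_candidate)
            b_end = place_base_vector(chosen.c1p, pair, grid)
            placed = fit_base(b_end, chosen.c1p, pair.p5, grid,
                              chi_curve=curves.pseudo_chi, w_chi=w_chi)
            if sequence is not None:
                # nucleotide index in sequence order
                idx = len(trace.anchors) - 1 if direction == "5to3" else length - 1 - len(trace.anchors)
                idx = int(np.clip(idx, 0, len(sequence) - 1))
                placed = mutate_base(placed, sequence[idx])
            placed = refine_orientation(
                placed, grid, curves.pseudo_chi, w_chi=w_chi,
                sugar_center=chosen.sugar.position,
            )
            cands[pick] = replace(cands[pick], base=placed)
        report.append(
            {
                "step": step,
                "status": "ok",
                "pick": pick,
                "candidates": [
                    {
                        "phosphate": c.p_candidate.tolist(),
                        "c1p": c.c1p.tolist(),
                        "s_overall": c.s_overall,
                        "components": c.component_scores,
                    }
                    for c in cands
                ],
            }
        )
        trace = extend_trace(trace, cands, pick)
        step += 1
    return trace, report
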