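"""RNA backbone suite conformer library, per-suite prediction and flags.

The backbone is divided into *suites*: units spanning two sugars and the
intervening phosphate, with torsions (delta-1, epsilon-1, zeta-1, alpha,
beta, gamma, delta).  The bundled consensus library enumerates ~50 named
discrete conformers (two-character codes such as ``1a`` for A-form), plus
six more recently promoted members (2g, 2u, 2z, 3g, 5n, 5r).  Adjacent
suites share a sugar, so the ending pucker of one suite must equal the
leading pucker of the next.

Suite conformers are predicted from phosphate and C1' anchor coordinates
alone.  The predictor implemented here is a Gaussian anchor-shape
classifier: each conformer's reference suite is forward-built from its
torsion means in a canonical flanking context, the five anchor atoms
(C1'[i-1], P[i], C1'[i], P[i+1], C1'[i+1]) are reduced to a
rotation-invariant shape vector (consecutive distances, planar angles and
the two pseudotorsions eta' and theta'), and each conformer is scored by an
independent Gaussian in that space.  Scores are normalized to sum to one
per suite.  The classifier is deliberately pluggable (see
:class:`SuiteClassifier`) so that a different prediction method can be
substituted without touching the callers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .geometry import angle, torsion

__all__ = [
    "ConformerDef",
    "ConformerLibrary",
    "SuiteAnchors",
    "SuitePrediction",
    "SuiteClassifier",
    "FlagThresholds",
    "load_library",
    "predict_suite",
    "flag_suite",
    "apply_alternate",
]


@dataclass(frozen=True)
class ConformerDef:
    """One named backbone conformer: 2-character code, mean torsions
    (delta-1, epsilon-1, zeta-1, alpha, beta, gamma, delta) and the sugar
    puckers its delta means imply."""

    name: str
    torsions: tuple[float, ...]
    leading_pucker: str
    ending_pucker: str
    promoted_wannabe: bool = False

    def __post_init__(self):
        if len(self.name) != 2:
            raise ValueError(f"conformer names are 2 characters, got {self.name!r}")
        if len(self.torsions) != 7:
            raise ValueError("a suite has 7 torsions")


class ConformerLibrary:
    """Mapping of conformer name -> :class:`ConformerDef`."""

    def __init__(self, defs: list[ConformerDef]):
        self._defs = {d.name: d for d in defs}
        if len(self._defs) != len(defs):
            raise ValueError("duplicate conformer names in library")

    def __getitem__(self, name: str) -> ConformerDef:
        return self._defs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs.values())

    def names(self) -> list[str]:
        return list(self._defs)


_LIBRARY_CACHE: ConformerLibrary | None = None


def load_library() -> ConformerLibrary:
    """Load the bundled consensus conformer library."""
    global _LIBRARY_CACHE
    if _LIBRARY_CACHE is None:
        text = resources.files("rnatrace.data").joinpath("conformers.json").read_text()
        raw = json.loads(text)
        _LIBRARY_CACHE = ConformerLibrary(
            [
                ConformerDef(
                    name=r["name"],
                    torsions=tuple(r["torsions"]),
                    leading_pucker=r["leading_pucker"],
                    ending_pucker=r["ending_pucker"],
                    promoted_wannabe=r.get("promoted_wannabe", False),
                )
                for r in raw["conformers"]
            ]
        )
    return _LIBRARY_CACHE


# ---------------------------------------------------------------------------
# suite anchors and shape features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SuiteAnchors:
    """The five anchor atoms the predictor sees for suite i:
    C1'[i-1], P[i], C1'[i], P[i+1], C1'[i+1]."""

    c1p_prev: np.ndarray
    p: np.ndarray
    c1p: np.ndarray
    p_next: np.ndarray
    c1p_next: np.ndarray

    def chain(self) -> np.ndarray:
        return np.array(
            [self.c1p_prev, self.p, self.c1p, self.p_next, self.c1p_next], dtype=float
        )

    def pseudotorsions(self) -> tuple[float, float]:
        """(eta', theta'): the C1'/P pseudotorsion pair around the suite."""
        pts = self.chain()
        return (
            torsion(pts[0], pts[1], pts[2], pts[3]),
            torsion(pts[1], pts[2], pts[3], pts[4]),
        )


#: feature order: 4 consecutive distances, 3 planar angles, eta', theta'
FEATURE_SCALES = np.array([0.45, 0.45, 0.45, 0.45, 6.0, 6.0, 6.0, 12.0, 12.0])
_ANGULAR = np.array([False] * 4 + [False] * 3 + [True, True])


def anchor_features(anchors: SuiteAnchors) -> np.ndarray:
    pts = anchors.chain()
    d = [np.linalg.norm(pts[i + 1] - pts[i]) for i in range(4)]
    a = [angle(pts[i], pts[i + 1], pts[i + 2]) for i in range(3)]
    eta, theta = anchors.pseudotorsions()
    return np.array(d + a + [eta, theta])


def _feature_distance2(f: np.ndarray, mu: np.ndarray) -> float:
    diff = f - mu
    diff[_ANGULAR] = (diff[_ANGULAR] + 180.0) % 360.0 - 180.0
    z = diff / FEATURE_SCALES
    return float(z @ z)


@dataclass(frozen=True)
class SuitePrediction:
    suite_index: int
    scores: dict[str, float]
    flag: str | None = None
    flag_reason: str | None = None

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def best(self) -> str:
        return self.ranked()[0][0]


class SuiteClassifier:
    """Gaussian anchor-shape classifier over the conformer library.

    Reference shape vectors are forward-built once per library from the
    conformer torsion means (lazily, via the synthetic-model builder) so
    the classifier is self-consistent with the coordinate machinery.
    """

    def __init__(self, library: ConformerLibrary | None = None):
        self.library = library or load_library()
        self._centroids: dict[str, np.ndarray] | None = None

    def centroids(self) -> dict[str, np.ndarray]:
        if self._centroids is None:
            from .fixtures import suite_anchor_reference  # deferred: avoids cycle

            self._centroids = {
                c.name: anchor_features(suite_anchor_reference(c)) for c in self.library
            }
        return self._centroids

    def score(self, anchors: SuiteAnchors) -> dict[str, float]:
        f = anchor_features(anchors)
        cents = self.centroids()
        logs = {name: -0.5 * _feature_distance2(f.copy(), mu) for name, mu in cents.items()}
        m = max(logs.values())
        raw = {name: np.exp(v - m) for name, v in logs.items()}
        total = sum(raw.values())
        return {name: v / total for name, v in raw.items()}


_DEFAULT_CLASSIFIER: SuiteClassifier | None = None


def default_classifier() -> SuiteClassifier:
    global _DEFAULT_CLASSIFIER
    if _DEFAULT_CLASSIFIER is None:
        _DEFAULT_CLASSIFIER = SuiteClassifier()
    return _DEFAULT_CLASSIFIER


def predict_suite(
    anchors: SuiteAnchors,
    suite_index: int = 0,
    classifier: SuiteClassifier | None = None,
) -> SuitePrediction:
    """Score every library conformer for one suite; scores sum to one."""
    classifier = classifier or default_classifier()
    scores = classifier.score(anchors)
    return SuitePrediction(suite_index=suite_index, scores=scores)


# ---------------------------------------------------------------------------
# traffic-light flags
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlagThresholds:
    """Prediction-ambiguity and build-mismatch flag thresholds.

    A suite is flagged when the runner-up conformer scores close to the
    winner (score2/score1 above the yellow/orange ratios) or when the
    built coordinates failed to match the assigned conformer (circular
    torsion residual above ``red_residual``, degrees).
    """

    yellow_ratio: float = 0.5
    orange_ratio: float = 0.72
    red_residual: float = 30.0


def flag_suite(
    pred: SuitePrediction,
    build_residual: float | None = None,
    thresholds: FlagThresholds = FlagThresholds(),
) -> SuitePrediction:
    """Attach a traffic-light flag to a prediction."""
    if build_residual is not None and build_residual > thresholds.red_residual:
        return replace(pred, flag="red", flag_reason="build-mismatch")
    ranked = pred.ranked()
    if len(ranked) >= 2 and ranked[0][1] > 0:
        ratio = ranked[1][1] / ranked[0][1]
        if ratio > thresholds.orange_ratio:
            return replace(pred, flag="orange", flag_reason="prediction-uncertainty")
        if ratio > thresholds.yellow_ratio:
            return replace(pred, flag="yellow", flag_reason="prediction-uncertainty")
    return replace(pred, flag=None, flag_reason=None)


def chain_assignment(
    score_maps: list[dict[str, float] | None],
    library: ConformerLibrary | None = None,
) -> list[str]:
    """Pucker-consistent conformer assignment over consecutive suites.

    Per-suite scores are combined by dynamic programming maximizing the sum
    of log scores subject to the invariant that the ending pucker of each
    suite equals the leading pucker of the next.  ``None`` entries (suites
    without predictions) are treated as uninformative.
    """
    library = library or load_library()
    confs = list(library)
    n = len(score_maps)
    if n == 0:
        return []
    eps = 1e-12

    def logscore(k: int, c: ConformerDef) -> float:
        sm = score_maps[k]
        if sm is None:
            return 0.0
        return float(np.log(max(sm.get(c.name, 0.0), eps)))

    best = [{c.name: (logscore(0, c), None) for c in confs}]
    for k in range(1, n):
        layer = {}
        for c in confs:
            cand = [
                (best[k - 1][p.name][0], p.name)
                for p in confs
                if p.ending_pucker == c.leading_pucker
            ]
            prev_score, prev_name = max(cand)
            layer[c.name] = (prev_score + logscore(k, c), prev_name)
        best.append(layer)
    end_name = max(best[-1], key=lambda nm: best[-1][nm][0])
    names = [end_name]
    for k in range(n - 1, 0, -1):
        names.append(best[k][names[-1]][1])
    return names[::-1]


def apply_alternate(model, suite_index: int, new_conformer: str, grid=None, **kwargs):
    """Reassign one suite to an alternate conformer and rebuild it.

    If the alternate changes a sugar pucker, the adjacent suite sharing
    that sugar is rebuilt too, keeping shared-pucker consistency.
    Delegates to the builder module.
    """
    from . import builder

    library = load_library()
    if new_conformer not in library:
        raise KeyError(f"unknown conformer {new_conformer!r}")
    return builder.rebuild_with_conformer(model, suite_index, new_conformer, grid=grid, **kwargs)
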