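"""Coordinate calculation by restrained minimization; rotamerization.

Given a backbone trace (phosphate positions plus fitted bases) and one
predicted conformer per suite, all-atom coordinates are computed by
quasi-Newton minimization of a restraint objective in Cartesian space:

* bond-length and bond-angle ideality terms;
* harmonic restraints on the seven suite torsions, targeted at the
  assigned conformer's mean torsions;
* strong restraints on the ribose nu0, nu1 and nu4 torsions with
  pucker-dependent ideal values (the sugar ring is flexible, not rigid);
* a strong harmonic position restraint keeping each phosphate near its
  traced location (the phosphate is not fixed outright);
* a weak electron-density term (weight 10) rewarding atoms sitting in
  density, deliberately much weaker than the geometry terms.

Base atoms are held fixed at their fitted positions and couple to the
backbone through the glycosidic bond/angle restraints.  Rotamerization
applies the same machinery to a stretch of an existing model, adding 5'
heminucleotide (alpha/beta/gamma) and 3' heminucleotide (epsilon/zeta)
torsion restraints taken from the existing structure so the junctions keep
their geometry.  Minimization is deterministic: the chain is initialized by
forward-building the assigned conformers onto the anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import constants
from .conformers import (
    ConformerLibrary,
    FlagThresholds,
    SuiteClassifier,
    SuitePrediction,
    default_classifier,
    flag_suite,
    load_library,
    predict_suite,
)
from .geometry import kabsch
from .model import SUITE_TORSION_ATOMS, NucleotideModel

log = logging.getLogger(__name__)

__all__ = [
    "BuilderWeights",
    "RestraintSet",
    "NucleotideModel",
    "build_suites",
    "rotamerize",
    "rebuild_with_conformer",
    "pucker_targets",
    "suite_residual",
]

B = constants.BOND_LENGTHS
A = constants.BOND_ANGLES

_NU_QUADS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


def pucker_targets(pucker: str) -> tuple[float, float, float]:
    """Ideal (nu0, nu1, nu4) restraint targets (deg) for a sugar pucker."""
    nus = constants.nu_targets(pucker)
    return float(nus[0]), float(nus[1]), float(nus[4])


@dataclass(frozen=True)
class BuilderWeights:
    """Objective weights.  The density weight is the published value 10;
    the geometry spring constants are calibrated so that on noise-free
    fixtures anchors are met within 0.3 Å and torsions within 5 deg."""

    k_bond: float = 300.0        # per Å^2
    k_angle: float = 50.0        # per rad^2
    k_suite_torsion: float = 20.0  # per rad^2
    k_pucker: float = 50.0       # per rad^2 ("strong" nu restraints)
    k_junction: float = 50.0     # per rad^2 (heminucleotide torsions)
    k_phosphate: float = 100.0   # per Å^2 (harmonic P anchor)
    density_weight: float = 10.0
    max_iterations: int = 500
    gradient_tolerance: float = 1e-4


@dataclass
class RestraintSet:
    """Vectorized restraint terms over a flattened atom array."""

    n_atoms: int
    bonds: list = field(default_factory=list)      # (i, j, l0, k)
    angles: list = field(default_factory=list)     # (i, j, k_, th0_deg, k)
    torsions: list = field(default_factory=list)   # (i, j, k_, l, phi0_deg, k)
    positions: list = field(default_factory=list)  # (i, xyz, k)
    density_atoms: list = field(default_factory=list)
    density_weight: float = 0.0
    grid: object | None = None

    def _packed(self):
        out = {}
        out["b"] = (
            np.array([[t[0], t[1]] for t in self.bonds], dtype=int).reshape(-1, 2),
            np.array([t[2] for t in self.bonds]),
            np.array([t[3] for t in self.bonds]),
        )
        out["a"] = (
            np.array([[t[0], t[1], t[2]] for t in self.angles], dtype=int).reshape(-1, 3),
            np.deg2rad([t[3] for t in self.angles]),
            np.array([t[4] for t in self.angles]),
        )
        out["t"] = (
            np.array([[t[0], t[1], t[2], t[3]] for t in self.torsions], dtype=int).reshape(-1, 4),
            np.deg2rad([t[4] for t in self.torsions]),
            np.array([t[5] for t in self.torsions]),
        )
        out["p"] = (
            np.array([t[0] for t in self.positions], dtype=int),
            np.array([t[1] for t in self.positions]).reshape(-1, 3),
            np.array([t[2] for t in self.positions]),
        )
        out["d"] = np.array(self.density_atoms, dtype=int)
        return out

    def energy_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        x = coords.reshape(-1, 3)
        grad = np.zeros_like(x)
        e = 0.0
        packed = self._packed()

        idx, l0, k = packed["b"]
        if len(idx):
            v = x[idx[:, 0]] - x[idx[:, 1]]
            r = np.linalg.norm(v, axis=1)
            diff = r - l0
            e += float(np.sum(k * diff**2))
            g = (2.0 * k * diff / np.maximum(r, 1e-12))[:, None] * v
            np.add.at(grad, idx[:, 0], g)
            np.add.at(grad, idx[:, 1], -g)

        idx, th0, k = packed["a"]
        if len(idx):
            u = x[idx[:, 0]] - x[idx[:, 1]]
            w = x[idx[:, 2]] - x[idx[:, 1]]
            nu = np.linalg.norm(u, axis=1)
            nw = np.linalg.norm(w, axis=1)
            uh = u / nu[:, None]
            wh = w / nw[:, None]
            cos = np.clip(np.sum(uh * wh, axis=1), -1.0, 1.0)
            th = np.arccos(cos)
            sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
            diff = th - th0
            e += float(np.sum(k * diff**2))
            dth_du = (cos[:, None] * uh - wh) / (nu * sin)[:, None]
            dth_dw = (cos[:, None] * wh - uh) / (nw * sin)[:, None]
            coef = (2.0 * k * diff)[:, None]
            np.add.at(grad, idx[:, 0], coef * dth_du)
            np.add.at(grad, idx[:, 2], coef * dth_dw)
            np.add.at(grad, idx[:, 1], -coef * (dth_du + dth_dw))

        idx, phi0, k = packed["t"]
        if len(idx):
            p1, p2, p3, p4 = (x[idx[:, m]] for m in range(4))
            b1 = p2 - p1
            b2 = p3 - p2
            b3 = p4 - p3
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / nb2[:, None])
            phi = np.arctan2(np.sum(m1 * n2, axis=1), np.sum(n1 * n2, axis=1))
            diff = np.arctan2(np.sin(phi - phi0), np.cos(phi - phi0))
            e += float(np.sum(k * diff**2))
            sq1 = np.sum(n1 * n1, axis=1)
            sq2 = np.sum(n2 * n2, axis=1)
            dphi_d1 = (nb2 / np.maximum(sq1, 1e-12))[:, None] * n1
            dphi_d4 = -(nb2 / np.maximum(sq2, 1e-12))[:, None] * n2
            d12 = np.sum(b1 * b2, axis=1) / np.maximum(nb2**2, 1e-12)
            d32 = np.sum(b3 * b2, axis=1) / np.maximum(nb2**2, 1e-12)
            dphi_d2 = (-1.0 - d12)[:, None] * dphi_d1 + d32[:, None] * dphi_d4
            dphi_d3 = (-1.0 - d32)[:, None] * dphi_d4 + d12[:, None] * dphi_d1
            coef = (2.0 * k * diff)[:, None]
            np.add.at(grad, idx[:, 0], coef * dphi_d1)
            np.add.at(grad, idx[:, 1], coef * dphi_d2)
            np.add.at(grad, idx[:, 2], coef * dphi_d3)
            np.add.at(grad, idx[:, 3], coef * dphi_d4)

        idx, targets, k = packed["p"]
        if len(idx):
            v = x[idx] - targets
            e += float(np.sum(k * np.sum(v * v, axis=1)))
            np.add.at(grad, idx, 2.0 * k[:, None] * v)

        didx = packed["d"]
        if len(didx) and self.grid is not None and self.density_weight > 0:
            vals, gr = self.grid.sample_with_gradient(x[didx])
            e -= self.density_weight * float(np.sum(vals))
            np.add.at(grad, didx, -self.density_weight * gr)

        return e, grad.reshape(-1)


def suite_residual(model: NucleotideModel, suite: int, conformer) -> float:
    """Circular r.m.s. deviation (deg) of a built suite's torsions from its
    assigned conformer's means."""
    lib = load_library()
    conf = lib[conformer] if isinstance(conformer, str) else conformer
    built = model.suite_torsions(suite)
    diff = (built - np.asarray(conf.torsions) + 180.0) % 360.0 - 180.0
    return float(np.sqrt(np.mean(diff**2)))


# ---------------------------------------------------------------------------
# restraint assembly
# ---------------------------------------------------------------------------


def _atom_index(model: NucleotideModel) -> tuple[dict[tuple[int, str], int], list]:
    index = {}
    order = []
    for i, res in enumerate(model.residues):
        for name in res:
            index[(i, name)] = len(order)
            order.append((i, name))
    return index, order


_INTRA_BONDS = [
    ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"), ("C4'", "C3'"),
    ("C3'", "O3'"), ("C3'", "C2'"), ("C2'", "C1'"), ("C1'", "O4'"),
    ("O4'", "C4'"), ("C2'", "O2'"),
]

_INTRA_ANGLES = [
    ("P", "O5'", "C5'"), ("O5'", "C5'", "C4'"), ("C5'", "C4'", "C3'"),
    ("C4'", "C3'", "O3'"), ("C2'", "C3'", "O3'"), ("C5'", "C4'", "O4'"),
    ("C1'", "C2'", "C3'"), ("C2'", "C3'", "C4'"), ("C3'", "C4'", "O4'"),
    ("C4'", "O4'", "C1'"), ("O4'", "C1'", "C2'"), ("C1'", "C2'", "O2'"),
    ("C3'", "C2'", "O2'"),
]


def _assemble(
    model: NucleotideModel,
    conformer_names: list[str | None],
    p_anchors: list[np.ndarray | None],
    grid,
    weights: BuilderWeights,
    free_resid: set[int],
    junction_torsions: list[tuple[tuple, float]] | None = None,
) -> tuple[RestraintSet, np.ndarray]:
    """Build the restraint set and the free-atom mask for a model.

    ``conformer_names[j-1]`` targets suite j; None skips that suite's
    torsion restraints.  ``junction_torsions`` holds extra
    (atom-path, target) pairs for heminucleotide restraints.
    """
    from .bases import load_templates

    lib = load_library()
    index, order = _atom_index(model)
    n = len(model)
    rs = RestraintSet(n_atoms=len(order))
    backbone = set(constants.BACKBONE_ATOMS) | set(constants.SUGAR_COMPLETION_ATOMS)

    def gi(i, name):
        return index[(i, name)]

    for i in range(n):
        res = model.residues[i]
        for a_, b_ in _INTRA_BONDS:
            if a_ in res and b_ in res:
                rs.bonds.append((gi(i, a_), gi(i, b_), B[(a_, b_)], weights.k_bond))
        for a_, b_, c_ in _INTRA_ANGLES:
            if a_ in res and b_ in res and c_ in res:
                rs.angles.append((gi(i, a_), gi(i, b_), gi(i, c_), A[(a_, b_, c_)], weights.k_angle))
        # glycosidic attachment to the (fixed) base
        tmpl = load_templates().get(model.sequence[i])
        if tmpl is not None and tmpl.glyco_atom in res:
            ng = tmpl.glyco_atom
            rs.bonds.append((gi(i, "C1'"), gi(i, ng), B[("C1'", "N")], weights.k_bond))
            rs.angles.append((gi(i, "O4'"), gi(i, "C1'"), gi(i, ng), A[("O4'", "C1'", "N")], weights.k_angle))
            rs.angles.append((gi(i, "C2'"), gi(i, "C1'"), gi(i, ng), A[("C2'", "C1'", "N")], weights.k_angle))
        if i + 1 < n:
            nxt = model.residues[i + 1]
            if "O3'" in res and "P" in nxt:
                rs.bonds.append((gi(i, "O3'"), gi(i + 1, "P"), B[("O3'", "P")], weights.k_bond))
                rs.angles.append((gi(i, "C3'"), gi(i, "O3'"), gi(i + 1, "P"), A[("C3'", "O3'", "P")], weights.k_angle))
                rs.angles.append((gi(i, "O3'"), gi(i + 1, "P"), gi(i + 1, "O5'"), A[("O3'", "P", "O5'")], weights.k_angle))

    # suite torsion restraints
    for j in range(1, n):
        name = conformer_names[j - 1] if j - 1 < len(conformer_names) else None
        if name is None:
            continue
        conf = lib[name]
        for path, target in zip(SUITE_TORSION_ATOMS, conf.torsions):
            atoms = [gi(j - 1 + off, nm) for nm, off in path]
            rs.torsions.append((*atoms, target, weights.k_suite_torsion))

    # pucker (nu) restraints for every sugar; pucker from the suite
    # assignments where available, else from the current coordinates
    for i in range(n):
        pucker = None
        if i < n - 1 and i < len(conformer_names) and conformer_names[i]:
            pucker = lib[conformer_names[i]].leading_pucker
        elif i >= 1 and conformer_names[i - 1]:
            pucker = lib[conformer_names[i - 1]].ending_pucker
        if pucker is None:
            try:
                pucker = model.pucker(i)
            except (KeyError, ValueError):
                continue
        nus = constants.nu_targets(pucker)
        for qi, quad in enumerate(_NU_QUADS):
            if qi not in (0, 1, 4):
                continue  # nu0, nu1, nu4 restrained; nu2/nu3 follow
            atoms = [gi(i, nm) for nm in quad]
            rs.torsions.append((*atoms, float(nus[qi]), weights.k_pucker))

    # harmonic phosphate anchors
    for i, anchor in enumerate(p_anchors):
        if anchor is not None and (i, "P") in index:
            rs.positions.append((gi(i, "P"), np.asarray(anchor, dtype=float), weights.k_phosphate))

    for path, target in junction_torsions or []:
        atoms = [gi(i, nm) for nm, i in path]
        rs.torsions.append((*atoms, target, weights.k_junction))

    free = np.zeros(len(order), dtype=bool)
    for (i, name), gidx in index.items():
        if i in free_resid and name in backbone:
            free[gidx] = True

    if grid is not None and weights.density_weight > 0:
        rs.density_atoms = list(np.nonzero(free)[0])
        rs.density_weight = weights.density_weight
        rs.grid = grid
    return rs, free


def _minimize(model: NucleotideModel, rs: RestraintSet, free: np.ndarray, weights: BuilderWeights) -> NucleotideModel:
    index, order = _atom_index(model)
    coords = np.array([model.residues[i][nm] for i, nm in order])
    x_full = coords.copy()
    free_idx = np.nonzero(free)[0]

    def fun(xf):
        x_full[free_idx] = xf.reshape(-1, 3)
        e, g = rs.energy_and_grad(x_full.reshape(-1))
        return e, g.reshape(-1, 3)[free_idx].reshape(-1)

    res = minimize(
        fun,
        coords[free_idx].reshape(-1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": weights.max_iterations, "gtol": weights.gradient_tolerance},
    )
    if not res.success:
        log.warning("minimization stopped early: %s", res.message)
    x_full[free_idx] = res.x.reshape(-1, 3)
    out = model.copy()
    for (i, nm), gidx in index.items():
        out.residues[i][nm] = x_full[gidx].copy()
    return out


# ---------------------------------------------------------------------------
# building from a trace
# ---------------------------------------------------------------------------


def build_suites(
    trace,
    predictions: list[SuitePrediction] | list[str] | None = None,
    grid=None,
    weights: BuilderWeights | None = None,
    sequence: str | None = None,
    classifier: SuiteClassifier | None = None,
    flag_thresholds=None,
) -> NucleotideModel:
    """Compute all-atom coordinates for a completed trace.

    ``predictions`` may be SuitePrediction objects, conformer names, or
    None (predict here with the default classifier).  Suites whose flanking
    anchors are missing fall back to the A-form conformer matching the
    junction puckers and are reported.
    """
    from .conformers import SuiteAnchors
    from .fixtures import SyntheticSpec, build_ideal_model

    weights = weights or BuilderWeights()
    anchors = trace.anchors_in_sequence_order()
    n = len(anchors)
    if n < 2:
        raise ValueError("need at least two anchors to build a nucleotide")
    p_anchors = [np.asarray(a.phosphate, dtype=float) for a in anchors]
    bases = [a.base for a in anchors]
    if sequence is None:
        sequence = "".join(
            (b.base_type if b is not None else "A") for b in bases
        )

    # conformer assignment per suite
    conf_names: list[str | None] = [None] * (n - 1)
    preds: list[SuitePrediction | None] = [None] * (n - 1)
    if predictions is not None and all(isinstance(p, str) for p in predictions):
        conf_names = list(predictions)
    else:
        supplied = {p.suite_index: p for p in predictions} if predictions else {}
        classifier = classifier or default_classifier()
        for j in range(1, n):
            if j in supplied:
                preds[j - 1] = supplied[j]
            elif 1 <= j <= n - 2:
                c1_prev = anchors[j - 1].c1p
                c1 = anchors[j].c1p
                c1_next = anchors[j + 1].c1p
                if c1_prev is None or c1 is None or c1_next is None:
                    continue
                sa = SuiteAnchors(
                    c1p_prev=c1_prev, p=p_anchors[j], c1p=c1,
                    p_next=p_anchors[j + 1], c1p_next=c1_next,
                )
                preds[j - 1] = predict_suite(sa, suite_index=j, classifier=classifier)
        # combine per-suite scores into a pucker-consistent assignment
        from .conformers import chain_assignment

        score_maps = [p.scores if p is not None else None for p in preds]
        conf_names = list(chain_assignment(score_maps))
        for k, p in enumerate(preds):
            if p is None:
                log.info("suite %d lacked anchors; assigned %s by chaining", k + 1, conf_names[k])
    lib = load_library()

    # initialize from an ideal forward build aligned onto the anchors
    init = build_ideal_model(SyntheticSpec(sequence=sequence, conformers=tuple(conf_names)))
    ref_pts = []
    mob_pts = []
    for i in range(n):
        ref_pts.append(p_anchors[i])
        mob_pts.append(init.atom(i, "P"))
        if anchors[i].c1p is not None:
            ref_pts.append(anchors[i].c1p)
            mob_pts.append(init.atom(i, "C1'"))
    rot, tr = kabsch(np.array(mob_pts), np.array(ref_pts))
    work = init.transformed(rot, tr)
    work.sequence = sequence

    # fitted bases replace the ideal ones and stay fixed
    for i, b in enumerate(bases):
        if b is None:
            continue
        for nm in work.base_atom_names(i):
            del work.residues[i][nm]
        for nm, pos in b.atoms.items():
            work.residues[i][nm] = np.asarray(pos, dtype=float)

    rs, free = _assemble(
        work, conf_names, p_anchors, grid, weights, free_resid=set(range(n))
    )
    built = _minimize(work, rs, free, weights)

    built.conformers = [c for c in conf_names]
    built.suite_residuals = [
        suite_residual(built, j, conf_names[j - 1]) for j in range(1, n)
    ]
    thresholds = flag_thresholds or FlagThresholds()
    built.suite_predictions = [
        flag_suite(p, build_residual=built.suite_residuals[k], thresholds=thresholds)
        if p is not None
        else None
        for k, p in enumerate(preds)
    ]
    return built


# ---------------------------------------------------------------------------
# rotamerization
# ---------------------------------------------------------------------------


def rotamerize(
    model: NucleotideModel,
    start: int,
    end: int,
    grid=None,
    classifier: SuiteClassifier | None = None,
    weights: BuilderWeights | None = None,
    conformer_overrides: dict[int, str] | None = None,
) -> NucleotideModel:
    """Rebuild nucleotides ``start``..``end`` (inclusive) of an existing
    model: re-predict their suites from the existing phosphate and C1'
    coordinates, then re-minimize with junction heminucleotide restraints
    (alpha/beta/gamma at the 5' side, epsilon/zeta at the 3' side, targeted
    at the pre-existing torsion values).  Atoms outside the rebuilt span
    are returned unchanged."""
    n = len(model)
    if not (0 <= start <= end < n):
        raise IndexError(f"nucleotide span {start}..{end} outside 0..{n - 1}")
    weights = weights or BuilderWeights()
    classifier = classifier or default_classifier()
    work = model.copy()

    lo = max(start - 1, 0)  # suite `start` involves the preceding sugar
    free_resid = set(range(lo, end + 1))
    suites = list(range(max(start, 1), end + 1))  # suite j joins nts j-1, j

    conf_names: list[str | None] = [None] * (n - 1)
    predictions = []
    overrides = conformer_overrides or {}
    for j in suites:
        if j in overrides:
            conf_names[j - 1] = overrides[j]
            continue
        try:
            sa = work.suite_anchors(j)
        except IndexError:
            log.info("suite %d lacks flanking anchors; keeping existing torsions", j)
            continue
        pred = predict_suite(sa, suite_index=j, classifier=classifier)
        predictions.append(pred)
        conf_names[j - 1] = pred.best

    junction = []
    existing = {j: model.suite_torsions(j) for j in range(1, n)}
    # alpha, beta, gamma of the first rebuilt nucleotide (5' junction)
    if lo >= 1:
        j5 = lo  # suite index whose alpha/beta/gamma belong to nucleotide lo
        for t_idx in (3, 4, 5):
            path = [(nm, lo - 1 + off) for nm, off in SUITE_TORSION_ATOMS[t_idx]]
            junction.append((path, float(existing[j5][t_idx])))
    # epsilon, zeta of the last rebuilt nucleotide (3' junction)
    if end + 1 < n:
        j3 = end + 1
        for t_idx in (1, 2):
            path = [(nm, end + off) for nm, off in SUITE_TORSION_ATOMS[t_idx]]
            junction.append((path, float(existing[j3][t_idx])))
    elif suites and suites[-1] == n - 1:
        log.info("3' heminucleotide absent at the chain terminus; restraints dropped")

    p_anchors: list[np.ndarray | None] = [None] * n
    for i in free_resid:
        p_anchors[i] = work.atom(i, "P").copy()

    rs, free = _assemble(
        work, conf_names, p_anchors, grid, weights,
        free_resid=free_resid, junction_torsions=junction,
    )
    built = _minimize(work, rs, free, weights)

    if built.conformers is None:
        built.conformers = [None] * (n - 1)
    built.suite_residuals = built.suite_residuals or [float("nan")] * (n - 1)
    for j in suites:
        if conf_names[j - 1] is not None:
            built.conformers[j - 1] = conf_names[j - 1]
            built.suite_residuals[j - 1] = suite_residual(built, j, conf_names[j - 1])
    return built


def rebuild_with_conformer(
    model: NucleotideModel,
    suite_index: int,
    new_conformer: str,
    grid=None,
    classifier: SuiteClassifier | None = None,
    weights: BuilderWeights | None = None,
) -> NucleotideModel:
    """Reassign one suite to ``new_conformer`` and rebuild it; adjacent
    suites are rebuilt too when the swap changes a shared sugar pucker."""
    lib = load_library()
    conf = lib[new_conformer]
    n = len(model)
    j = suite_index
    if not 1 <= j <= n - 1:
        raise IndexError(f"suite {j} out of range")
    old_name = model.conformers[j - 1] if model.conformers else None
    old = lib[old_name] if old_name else None
    # rotamerize(start, end) rebuilds suites start..end (and frees
    # nucleotides start-1..end); a single-suite swap is the span (j, j)
    start, end = j, j
    overrides = {j: new_conformer}
    if old is not None:
        if old.leading_pucker != conf.leading_pucker and j - 1 >= 1:
            start = j - 1
            overrides[j - 1] = _compatible(lib, model, j - 1, ending=conf.leading_pucker)
        if old.ending_pucker != conf.ending_pucker and j + 1 <= n - 1:
            end = j + 1
            overrides[j + 1] = _compatible(lib, model, j + 1, leading=conf.ending_pucker)
    return rotamerize(
        model, start, end, grid=grid, classifier=classifier, weights=weights,
        conformer_overrides=overrides,
    )


def _compatible(lib: ConformerLibrary, model: NucleotideModel, j: int,
                leading: str | None = None, ending: str | None = None) -> str:
    """Best existing-assignment-compatible conformer for suite j under a
    pucker constraint: keep the current one if it fits, else re-predict
    among compatible conformers, else fall back to the A-form-like one."""
    current = model.conformers[j - 1] if model.conformers else None
    if current:
        c = lib[current]
        if (leading is None or c.leading_pucker == leading) and (
            ending is None or c.ending_pucker == ending
        ):
            return current
    try:
        sa = model.suite_anchors(j)
        scores = default_classifier().score(sa)
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        for name, _ in ranked:
            c = lib[name]
            if (leading is None or c.leading_pucker == leading) and (
                ending is None or c.ending_pucker == ending
            ):
                return name
    except IndexError:
        pass
    if leading == "C2'-endo" or ending == "C2'-endo":
        return "2a" if leading == "C2'-endo" else "1b"
    return "1a"
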