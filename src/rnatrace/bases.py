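"""Placing, fitting, mutating and flipping nucleoside bases in density.

A base is first approximated by a single 5 Å probe vector anchored at the
candidate C1' atom (roughly the C1'->C4 span of a pyrimidine).  The probe
direction is chosen to maximize density along the vector, constrained to
point away from the backbone: the angle between the probe and the bisector
of C1'->P5' and C1'->P3' must lie in [90 deg, 180 deg].  A pyrimidine is
then laid along the probe and spun about it to maximize

    s_base = s_ring_density + w_chi * s_pseudo-chi,

the summed density at its ring atoms plus a prior on the pseudo-chi torsion
(P-C1'-N1-N3 for pyrimidines, P-C1'-N9-N1 for purines).  Finally the base
is computationally mutated to the requested type: purine ring systems are
aligned ring-on-ring, and purine<->pyrimidine swaps align the purine
C4-C5 bond midpoint with the pyrimidine's C1'->C4 direction while keeping
the base plane, so the new base occupies the same density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .geometry import angle, kabsch, torsion

__all__ = [
    "BaseTemplate",
    "PlacedBase",
    "load_templates",
    "place_base_vector",
    "fit_base",
    "mutate_base",
    "flip_base",
    "base_rmsd",
    "PROBE_LENGTH",
]

PROBE_LENGTH = 5.0  # Å, ~ C1'-C4 span of a pyrimidine


def _chi_score(chi_curve, x) -> float:
    """Pseudo-chi prior in likelihood-ratio units (unit maximum), so it is
    commensurable with sigma-scaled ring-density sums in s_base."""
    peak = float(chi_curve.density.max())
    return float(chi_curve.eval(x)) / peak if peak > 0 else 0.0


@dataclass(frozen=True)
class BaseTemplate:
    """Ideal planar base geometry in a canonical in-plane frame:
    the glycosidic C1' at the origin, the glycosidic nitrogen on +x."""

    base_type: str
    atoms2d: dict[str, np.ndarray]  # includes the "C1'" pseudo-atom at origin
    ring_atoms: tuple[str, ...]
    glyco_atom: str
    frame_atoms: tuple[str, str, str]
    chi_partner: str
    pseudo_chi_base_atoms: tuple[str, str]

    @property
    def is_purine(self) -> bool:
        return self.glyco_atom == "N9"

    def atom_names(self) -> list[str]:
        return [n for n in self.atoms2d if n != "C1'"]

    def c4c5_mid2d(self) -> np.ndarray:
        return (self.atoms2d["C4"] + self.atoms2d["C5"]) / 2.0

    def place(self, c1p: np.ndarray, ex: np.ndarray, ey: np.ndarray) -> dict[str, np.ndarray]:
        """Realize the template in 3D on the plane spanned by orthonormal
        in-plane axes (ex, ey) with C1' at ``c1p``; the template's +x maps
        to ex."""
        return {
            n: c1p + p[0] * ex + p[1] * ey
            for n, p in self.atoms2d.items()
            if n != "C1'"
        }


_TEMPLATE_CACHE: dict[str, BaseTemplate] | None = None


def load_templates() -> dict[str, BaseTemplate]:
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is None:
        raw = json.loads(
            resources.files("rnatrace.data").joinpath("base_templates.json").read_text()
        )
        out = {}
        for name, b in raw["bases"].items():
            out[name] = BaseTemplate(
                base_type=name,
                atoms2d={k: np.asarray(v, dtype=float) for k, v in b["atoms"].items()},
                ring_atoms=tuple(b["ring_atoms"]),
                glyco_atom=b["glyco_atom"],
                frame_atoms=tuple(b["frame_atoms"]),
                chi_partner=b["chi_partner"],
                pseudo_chi_base_atoms=tuple(b["pseudo_chi_base_atoms"]),
            )
        _TEMPLATE_CACHE = out
    return _TEMPLATE_CACHE


@dataclass(frozen=True)
class PlacedBase:
    """A base realized in 3D, together with its anchors and fit scores."""

    base_type: str
    atoms: dict[str, np.ndarray]
    c1p: np.ndarray
    p: np.ndarray | None = None
    b_end: np.ndarray | None = None
    s_ring_density: float | None = None
    s_pseudo_chi: float | None = None

    @property
    def template(self) -> BaseTemplate:
        return load_templates()[self.base_type]

    def ring_coords(self) -> np.ndarray:
        return np.array([self.atoms[n] for n in self.template.ring_atoms])

    def plane_normal(self) -> np.ndarray:
        ring = self.ring_coords()
        centered = ring - ring.mean(axis=0)
        # smallest principal axis of the (near-planar) ring
        _, _, vt = np.linalg.svd(centered)
        return vt[2]

    def pseudo_chi(self) -> float:
        if self.p is None:
            raise ValueError("pseudo-chi requires the 5' phosphate anchor")
        a1, a2 = self.template.pseudo_chi_base_atoms
        return torsion(self.p, self.c1p, self.atoms[a1], self.atoms[a2])

    def c4c5_mid(self) -> np.ndarray:
        return (self.atoms["C4"] + self.atoms["C5"]) / 2.0


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    trial = np.eye(3)[np.argmin(np.abs(u))]
    a = np.cross(u, trial)
    a /= np.linalg.norm(a)
    return a, np.cross(u, a)


def place_base_vector(
    c1p: np.ndarray,
    pair,
    grid,
    probe_length: float = PROBE_LENGTH,
    n_samples: int = 10,
    pitch_deg: float = 5.0,
) -> np.ndarray:
    """Choose the probe endpoint b on the sphere of radius ``probe_length``
    about C1' maximizing segment density, with the angle between C1'->b and
    the phosphate bisector in [90, 180] deg.  Grid scan (polar pitch as
    given) plus a fine local rescan; ties resolve to the first maximizer in
    scan order."""
    from .density import sample_segment_density

    c1p = np.asarray(c1p, dtype=float)
    bis = (pair.p5 - c1p) / np.linalg.norm(pair.p5 - c1p) + (pair.p3 - c1p) / np.linalg.norm(
        pair.p3 - c1p
    )
    nb = np.linalg.norm(bis)
    if nb < 1e-9:
        raise ValueError("degenerate phosphate bisector at C1'")
    bis /= nb
    e1, e2 = _perp_basis(bis)

    def direction(theta_deg: float, phi_deg: float) -> np.ndarray:
        th = np.deg2rad(theta_deg)
        ph = np.deg2rad(phi_deg)
        return np.cos(th) * bis + np.sin(th) * (np.cos(ph) * e1 + np.sin(ph) * e2)

    def scan(thetas, phis):
        best = None
        for th in thetas:
            for ph in phis:
                u = direction(th, ph)
                val = sample_segment_density(grid, c1p, c1p + probe_length * u, n_samples)
                if best is None or val > best[0]:
                    best = (val, th, ph)
        return best

    thetas = np.arange(90.0, 180.0 + 1e-9, pitch_deg)
    phis = np.arange(0.0, 360.0, pitch_deg)
    _, th0, ph0 = scan(thetas, phis)
    fine_th = np.clip(np.arange(th0 - pitch_deg, th0 + pitch_deg + 1e-9, 1.0), 90.0, 180.0)
    fine_ph = np.arange(ph0 - pitch_deg, ph0 + pitch_deg + 1e-9, 1.0)
    _, th1, ph1 = scan(fine_th, fine_ph)
    return c1p + probe_length * direction(th1, ph1)


def fit_base(
    b_end: np.ndarray,
    c1p: np.ndarray,
    p: np.ndarray,
    grid,
    template: BaseTemplate | None = None,
    chi_curve=None,
    w_chi: float = 1.0,
    scan_step_deg: float = 5.0,
) -> PlacedBase:
    """Lay a pyrimidine along C1'->b_end (C4 on the ray) and spin it about
    that axis to maximize ring density plus the pseudo-chi prior."""
    templates = load_templates()
    template = template or templates["C"]
    if template.is_purine:
        raise ValueError("initial fitting uses a pyrimidine template")
    c1p = np.asarray(c1p, dtype=float)
    b_end = np.asarray(b_end, dtype=float)
    u = b_end - c1p
    u /= np.linalg.norm(u)
    a, b = _perp_basis(u)

    # template 2D frame rotated so +x points C1'->C4
    e_c4 = template.atoms2d["C4"] / np.linalg.norm(template.atoms2d["C4"])
    perp = np.array([-e_c4[1], e_c4[0]])
    coords2 = {n: np.array([p2 @ e_c4, p2 @ perp]) for n, p2 in template.atoms2d.items()}

    pc_a1, pc_a2 = template.pseudo_chi_base_atoms

    def realize(psi_deg: float) -> dict[str, np.ndarray]:
        psi = np.deg2rad(psi_deg)
        w = np.cos(psi) * a + np.sin(psi) * b
        return {n: c1p + q[0] * u + q[1] * w for n, q in coords2.items() if n != "C1'"}

    def score(psi_deg: float) -> tuple[float, float, float]:
        atoms = realize(psi_deg)
        ring = np.array([atoms[n] for n in template.ring_atoms])
        s_ring = float(np.sum(grid.sample(ring)))
        s_chi = 0.0
        if chi_curve is not None:
            pchi = torsion(p, c1p, atoms[pc_a1], atoms[pc_a2])
            s_chi = _chi_score(chi_curve, pchi)
        return s_ring + w_chi * s_chi, s_ring, s_chi

    psis = np.arange(0.0, 360.0, scan_step_deg)
    vals = [score(psi)[0] for psi in psis]
    best = int(np.argmax(vals))
    fine = np.arange(psis[best] - scan_step_deg, psis[best] + scan_step_deg + 1e-9, 1.0)
    fvals = [score(psi)[0] for psi in fine]
    fbest = int(np.argmax(fvals))
    psi_opt = fine[fbest] if fvals[fbest] >= vals[best] else psis[best]
    _, s_ring, s_chi = score(psi_opt)
    return PlacedBase(
        base_type=template.base_type,
        atoms=realize(psi_opt),
        c1p=c1p,
        p=np.asarray(p, dtype=float),
        b_end=b_end,
        s_ring_density=s_ring,
        s_pseudo_chi=s_chi,
    )


def _plane_axes(placed: PlacedBase, x_target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal axes of ``placed``'s base plane with ex along
    the (projected) ``x_target`` direction."""
    n = placed.plane_normal()
    ex = x_target - (x_target @ n) * n
    ex /= np.linalg.norm(ex)
    ey = np.cross(n, ex)
    return ex, ey


def mutate_base(placed: PlacedBase, target: str) -> PlacedBase:
    """Mutate a placed base to ``target`` type in place in the density.

    Same ring system: ring atoms keep their fitted coordinates and only the
    exocyclic substituents are rebuilt.  Purine<->pyrimidine: the new base
    is drawn in the same plane with the purine C4-C5 bond midpoint on the
    pyrimidine's C1'->C4 direction, glycosidic nitrogens on the same side.
    """
    templates = load_templates()
    if target not in templates:
        raise ValueError(f"unknown base type {target!r}")
    if target == placed.base_type:
        return placed
    src_t = placed.template
    tgt_t = templates[target]

    if src_t.is_purine == tgt_t.is_purine:
        # keep the fitted ring; rebuild substituents from the target template
        ref = [placed.atoms[nm] for nm in tgt_t.frame_atoms]
        tpl = [np.append(tgt_t.atoms2d[nm], 0.0) for nm in tgt_t.frame_atoms]
        rot, tr = kabsch(np.array(tpl), np.array(ref))
        atoms = {nm: placed.atoms[nm].copy() for nm in tgt_t.ring_atoms}
        for nm, p2 in tgt_t.atoms2d.items():
            if nm in atoms or nm == "C1'":
                continue
            atoms[nm] = rot @ np.append(p2, 0.0) + tr
        return replace(placed, base_type=target, atoms=atoms)

    if src_t.is_purine:
        # purine -> pyrimidine: pyrimidine C1'->C4 along C1'->mid(C4-C5)
        x_dir = placed.c4c5_mid() - placed.c1p
        glyco_ref = placed.atoms[src_t.glyco_atom]
        tpl2 = tgt_t.atoms2d
        e_ref = tpl2["C4"] / np.linalg.norm(tpl2["C4"])
    else:
        # pyrimidine -> purine: purine mid(C4-C5) along C1'->C4
        x_dir = placed.atoms["C4"] - placed.c1p
        glyco_ref = placed.atoms[src_t.glyco_atom]
        tpl2 = tgt_t.atoms2d
        mid = tgt_t.c4c5_mid2d()
        e_ref = mid / np.linalg.norm(mid)

    perp2 = np.array([-e_ref[1], e_ref[0]])
    coords2 = {n: np.array([q @ e_ref, q @ perp2]) for n, q in tpl2.items()}
    ex, ey = _plane_axes(placed, x_dir)
    options = []
    for sign in (1.0, -1.0):
        atoms = {
            n: placed.c1p + q[0] * ex + sign * q[1] * ey
            for n, q in coords2.items()
            if n != "C1'"
        }
        options.append(atoms)

    # the in-plane mirror is resolved by pseudo-chi agreement: the source
    # and target orientation descriptors (P-C1'-N9-N1 / P-C1'-N1-N3) must
    # match.  The glycosidic nitrogen itself sits almost on the alignment
    # axis, so nearest-N would be ill-conditioned.
    def orientation_mismatch(atoms) -> float:
        if placed.p is not None:
            a1, a2 = tgt_t.pseudo_chi_base_atoms
            chi_new = torsion(placed.p, placed.c1p, atoms[a1], atoms[a2])
            s1, s2 = src_t.pseudo_chi_base_atoms
            chi_old = torsion(placed.p, placed.c1p, placed.atoms[s1], placed.atoms[s2])
            return abs((chi_new - chi_old + 180.0) % 360.0 - 180.0)
        return float(np.linalg.norm(atoms[tgt_t.glyco_atom] - glyco_ref))

    picked = min(options, key=orientation_mismatch)
    return replace(placed, base_type=target, atoms=picked)


def _rotate_about_axis(points: dict[str, np.ndarray], origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> dict[str, np.ndarray]:
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    k = axis
    out = {}
    for n, pnt in points.items():
        v = pnt - origin
        vr = (
            v * np.cos(th)
            + np.cross(k, v) * np.sin(th)
            + k * (k @ v) * (1 - np.cos(th))
        )
        out[n] = origin + vr
    return out


def flip_base(placed: PlacedBase) -> PlacedBase:
    """Flip between anti and syn.  Pyrimidines rotate 180 deg about
    C1'->mid(C4-C5) (which keeps the ring inside its density); purines,
    being roughly symmetric about the glycosidic bond, rotate about chi."""
    t = placed.template
    if t.is_purine:
        axis = placed.atoms[t.glyco_atom] - placed.c1p
    else:
        axis = placed.c4c5_mid() - placed.c1p
    atoms = _rotate_about_axis(placed.atoms, placed.c1p, axis, 180.0)
    return replace(placed, atoms=atoms)


#: angle (deg) between the sugar-centroid->C1' extension and the glycosidic
#: bond in an ideal nucleoside (a consequence of the ideal glycosidic
#: attachment angles and ring geometry)
GLYCO_CENTROID_ANGLE = 119.5


def refine_orientation(
    placed: PlacedBase,
    grid,
    chi_curve=None,
    w_chi: float = 1.0,
    sugar_center=None,
    w_geo: float = 5.0,
    geo_width_deg: float = 10.0,
) -> PlacedBase:
    """Resolve the discrete orientation ambiguity of a fitted base.

    The pyrimidine used for the rotational fit is nearly two-fold symmetric
    in density, so the fitted base (especially after mutation) can land in
    a mirrored orientation.  The four variants generated by 180 deg
    rotations about the C1'->mid(C4-C5) and glycosidic axes are scored
    against density at all base atoms plus the pseudo-chi prior; when the
    traced sugar center is supplied, a geometric prior on the
    glycosidic-bond direction (angle G-C1'-N near its ideal value) breaks
    density-degenerate mirrors.  This is the batch-mode stand-in for
    interactive review of base flips.
    """
    t = placed.template
    axis_mid = placed.c4c5_mid() - placed.c1p
    axis_gly = placed.atoms[t.glyco_atom] - placed.c1p
    variants = [placed.atoms]
    variants.append(_rotate_about_axis(placed.atoms, placed.c1p, axis_mid, 180.0))
    variants.append(_rotate_about_axis(placed.atoms, placed.c1p, axis_gly, 180.0))
    variants.append(_rotate_about_axis(variants[1], placed.c1p, axis_gly, 180.0))

    def score(atoms) -> tuple[float, float, float]:
        pts = np.array(list(atoms.values()))
        s_ring = float(np.sum(grid.sample(pts)))
        s_chi = 0.0
        if chi_curve is not None and placed.p is not None:
            a1, a2 = t.pseudo_chi_base_atoms
            s_chi = _chi_score(
                chi_curve, torsion(placed.p, placed.c1p, atoms[a1], atoms[a2])
            )
        s = s_ring + w_chi * s_chi
        if sugar_center is not None:
            a = angle(sugar_center, placed.c1p, atoms[t.glyco_atom])
            s += w_geo * float(
                np.exp(-0.5 * ((a - GLYCO_CENTROID_ANGLE) / geo_width_deg) ** 2)
            )
        return s, s_ring, s_chi

    scored = [(score(v), i) for i, v in enumerate(variants)]
    (best, s_ring, s_chi), idx = max(scored, key=lambda sv: sv[0][0])
    return replace(
        placed, atoms=variants[idx], s_ring_density=s_ring, s_pseudo_chi=s_chi
    )


def base_rmsd(a: dict[str, np.ndarray], b: dict[str, np.ndarray], names=None) -> float:
    """Plain coordinate r.m.s.d. over atoms common to both bases."""
    names = names or sorted(set(a) & set(b))
    if not names:
        raise ValueError("no common atoms")
    d = np.array([a[n] - b[n] for n in names])
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
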