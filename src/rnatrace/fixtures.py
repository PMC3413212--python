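"""Synthetic ground truth: ideal RNA models and simulated density maps.

Models are forward-built in internal coordinates: the backbone chain
P-O5'-C5'-C4'-C3'-O3' is grown nucleotide by nucleotide from suite torsion
means (natural-extension placement), each ribose ring is completed by a
small least-squares solve against ideal ring geometry and pseudorotation
targets for its pucker, and bases are attached at a glycosidic torsion chi.
Simulated maps place an isotropic Gaussian of width derived from a
B-factor-like blur at every atom, weighted by atomic number (so phosphates
dominate, as they do in experimental maps), with optional seeded white
noise.  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from . import constants
from .bases import load_templates
from .conformers import ConformerDef, SuiteAnchors, load_library
from .density import DensityGrid
from .geometry import kabsch, place_atom, torsion
from .model import NucleotideModel

__all__ = [
    "SyntheticSpec",
    "build_ideal_model",
    "build_from_torsions",
    "simulate_map",
    "suite_anchor_reference",
    "reference_models",
    "jitter_anchors",
    "CONTEXT_SUITE_NAME",
]

B = constants.BOND_LENGTHS
A = constants.BOND_ANGLES

#: canonical continuation suites used where a chain needs torsions outside
#: any requested suite (first-nucleotide alpha/beta/gamma, downstream context)
CONTEXT_SUITE_NAME = {"C3'-endo": "1a", "C2'-endo": "2a"}

#: intrinsic atomic Gaussian width (Å) before blur is added
ATOM_SIGMA0 = 0.6


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic model/map pair.

    ``conformers`` is a concatenated string of 2-character suite names
    (length 2*(len(sequence)-1)) or a list of names; ``blur_b`` is a
    B-factor-like blur in Å² (the default 40 gives a Gaussian width
    matching a ~3 Å-resolution map via sigma = resolution/pi);
    ``noise_sd`` is white-noise SD in units of the clean map's sigma.
    """

    sequence: str
    conformers: str | tuple[str, ...] = ()
    blur_b: float = 40.0
    noise_sd: float = 0.0
    voxel: float = 0.5
    seed: int = 0
    pad: float = 4.5

    def conformer_names(self) -> list[str]:
        c = self.conformers
        if isinstance(c, str):
            names = [c[i : i + 2] for i in range(0, len(c), 2)]
        else:
            names = list(c)
        if not names and len(self.sequence) > 1:
            names = ["1a"] * (len(self.sequence) - 1)
        if len(names) != max(len(self.sequence) - 1, 0):
            raise ValueError("need one conformer per suite (len(sequence)-1)")
        return names


# ---------------------------------------------------------------------------
# ribose construction
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _sugar_template(pucker: str) -> dict[str, np.ndarray]:
    """Ideal ribose (plus C5', O3', O2') for one pucker, built once by
    least squares against ring geometry and pseudorotation targets."""
    nus = constants.nu_targets(pucker)
    delta = constants.DELTA_C3_ENDO if pucker == "C3'-endo" else constants.DELTA_C2_ENDO

    # rough start: grow the ring by internal coordinates, then refine
    c1 = np.zeros(3)
    c2 = np.array([B[("C2'", "C1'")], 0.0, 0.0])
    c3 = place_atom(np.array([0.0, 1.0, 0.0]), c1, c2, B[("C3'", "C2'")], A[("C1'", "C2'", "C3'")], 57.0)
    c4 = place_atom(c1, c2, c3, B[("C4'", "C3'")], A[("C2'", "C3'", "C4'")], nus[2])
    o4 = place_atom(c2, c3, c4, B[("O4'", "C4'")], A[("C3'", "C4'", "O4'")], nus[3])
    c5 = place_atom(c2, c3, c4, B[("C5'", "C4'")], A[("C5'", "C4'", "C3'")], nus[3] - 121.0)
    o3 = place_atom(c5, c4, c3, B[("C3'", "O3'")], A[("C4'", "C3'", "O3'")], delta)
    o2 = place_atom(c4, c3, c2, B[("C2'", "O2'")], A[("C3'", "C2'", "O2'")], nus[2] - 119.0)
    names = ["C1'", "C2'", "C3'", "C4'", "O4'", "C5'", "O3'", "O2'"]
    init = dict(zip(names, [c1, c2, c3, c4, o4, c5, o3, o2]))

    bonds = [
        ("C1'", "C2'", B[("C2'", "C1'")]),
        ("C2'", "C3'", B[("C3'", "C2'")]),
        ("C3'", "C4'", B[("C4'", "C3'")]),
        ("C4'", "O4'", B[("O4'", "C4'")]),
        ("O4'", "C1'", B[("C1'", "O4'")]),
        ("C4'", "C5'", B[("C5'", "C4'")]),
        ("C3'", "O3'", B[("C3'", "O3'")]),
        ("C2'", "O2'", B[("C2'", "O2'")]),
    ]
    angles = [
        ("C1'", "C2'", "C3'"), ("C2'", "C3'", "C4'"), ("C3'", "C4'", "O4'"),
        ("C4'", "O4'", "C1'"), ("O4'", "C1'", "C2'"), ("C5'", "C4'", "C3'"),
        ("C5'", "C4'", "O4'"), ("C4'", "C3'", "O3'"), ("C2'", "C3'", "O3'"),
        ("C1'", "C2'", "O2'"), ("C3'", "C2'", "O2'"),
    ]
    nu_quads = [
        ("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
        ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
        ("C3'", "C4'", "O4'", "C1'"),
    ]

    idx = {n: i for i, n in enumerate(names)}
    x0 = np.concatenate([init[n] for n in names])

    def residuals(x):
        pts = x.reshape(-1, 3)
        res = []
        for a_, b_, l0 in bonds:
            res.append(30.0 * (np.linalg.norm(pts[idx[a_]] - pts[idx[b_]]) - l0))
        for a_, b_, c_ in angles:
            u = pts[idx[a_]] - pts[idx[b_]]
            v = pts[idx[c_]] - pts[idx[b_]]
            cosv = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            res.append(8.0 * (np.arccos(np.clip(cosv, -1, 1)) - np.deg2rad(A[(a_, b_, c_)])))
        for q, target in zip(nu_quads, nus):
            t = torsion(*(pts[idx[n]] for n in q))
            res.append(4.0 * np.deg2rad((t - target + 180.0) % 360.0 - 180.0))
        t = torsion(pts[idx["C5'"]], pts[idx["C4'"]], pts[idx["C3'"]], pts[idx["O3'"]])
        res.append(4.0 * np.deg2rad((t - delta + 180.0) % 360.0 - 180.0))
        return np.array(res)

    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    pts = sol.x.reshape(-1, 3)
    out = {n: pts[idx[n]] for n in names}
    # O2' must sit on the alpha face (opposite C5'/base): enforce by mirror
    if _beta_side(out, out["O2'"]) > 0:
        out["O2'"] = _mirror_through_ring_plane(out, out["O2'"])
    return out


def _ring_normal(atoms: dict[str, np.ndarray]) -> np.ndarray:
    ring = np.array([atoms[n] for n in constants.RIBOSE_RING_ATOMS])
    centered = ring - ring.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[2]
    if n @ (atoms["C5'"] - atoms["C4'"]) < 0:
        n = -n
    return n  # points toward the beta (base) face


def _beta_side(atoms: dict[str, np.ndarray], point: np.ndarray) -> float:
    ring = np.array([atoms[n] for n in constants.RIBOSE_RING_ATOMS])
    return float(_ring_normal(atoms) @ (point - ring.mean(axis=0)))


def _mirror_through_ring_plane(atoms: dict[str, np.ndarray], point: np.ndarray) -> np.ndarray:
    host = atoms["C2'"]
    n = _ring_normal(atoms)
    v = point - host
    return host + v - 2.0 * (v @ n) * n


def _complete_sugar(res: dict[str, np.ndarray], pucker: str) -> None:
    """Fill C2', C1', O4', O2' given placed C5', C4', C3', O3'."""
    tmpl = _sugar_template(pucker)
    anchor_names = ["C5'", "C4'", "C3'", "O3'"]
    rot, tr = kabsch(
        np.array([tmpl[n] for n in anchor_names]),
        np.array([res[n] for n in anchor_names]),
    )
    for n in ("C2'", "C1'", "O4'", "O2'"):
        res[n] = rot @ tmpl[n] + tr

    nus = constants.nu_targets(pucker)
    names = ["C2'", "C1'", "O4'"]
    idx = {n: i for i, n in enumerate(names)}
    fixed = {k: res[k] for k in anchor_names}
    x0 = np.concatenate([res[n] for n in names])

    bonds = [("C3'", "C2'", B[("C3'", "C2'")]), ("C2'", "C1'", B[("C2'", "C1'")]),
             ("C1'", "O4'", B[("C1'", "O4'")]), ("O4'", "C4'", B[("O4'", "C4'")])]
    angles = [("C2'", "C3'", "C4'"), ("C1'", "C2'", "C3'"), ("O4'", "C1'", "C2'"),
              ("C4'", "O4'", "C1'"), ("C3'", "C4'", "O4'"), ("C2'", "C3'", "O3'"),
              ("C5'", "C4'", "O4'")]
    nu_quads = [("C4'", "O4'", "C1'", "C2'"), ("O4'", "C1'", "C2'", "C3'"),
                ("C1'", "C2'", "C3'", "C4'"), ("C2'", "C3'", "C4'", "O4'"),
                ("C3'", "C4'", "O4'", "C1'")]

    def get(pts, n):
        return fixed[n] if n in fixed else pts[idx[n]]

    def residuals(x):
        pts = x.reshape(-1, 3)
        out = []
        for a_, b_, l0 in bonds:
            out.append(30.0 * (np.linalg.norm(get(pts, a_) - get(pts, b_)) - l0))
        for a_, b_, c_ in angles:
            key = (a_, b_, c_) if (a_, b_, c_) in A else (c_, b_, a_)
            u = get(pts, a_) - get(pts, b_)
            v = get(pts, c_) - get(pts, b_)
            cosv = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            out.append(8.0 * (np.arccos(np.clip(cosv, -1, 1)) - np.deg2rad(A[key])))
        for q, target in zip(nu_quads, nus):
            t = torsion(*(get(pts, n) for n in q))
            out.append(4.0 * np.deg2rad((t - target + 180.0) % 360.0 - 180.0))
        return np.array(out)

    sol = least_squares(residuals, x0, xtol=1e-12, ftol=1e-12)
    pts = sol.x.reshape(-1, 3)
    for n in names:
        res[n] = pts[idx[n]]
    o2 = place_atom(res["C4'"], res["C3'"], res["C2'"],
                    B[("C2'", "O2'")], A[("C3'", "C2'", "O2'")],
                    torsion(res["C1'"], res["C2'"], res["C3'"], res["C4'"]) + 119.0)
    if _beta_side(res, o2) > 0:
        o2 = _mirror_through_ring_plane(res, o2)
    res["O2'"] = o2


def _attach_base(res: dict[str, np.ndarray], base_type: str, chi: float) -> None:
    """Place the base: glycosidic N on the beta face at ideal angles, ring
    realized from the planar template at the glycosidic torsion chi
    (O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines)."""
    tmpl = load_templates()[base_type]
    c1, o4, c2s = res["C1'"], res["O4'"], res["C2'"]
    u1 = o4 - c1
    u1 /= np.linalg.norm(u1)
    u2 = c2s - c1
    u2 /= np.linalg.norm(u2)
    nrm = np.cross(u1, u2)
    nrm /= np.linalg.norm(nrm)
    t1 = np.cos(np.deg2rad(A[("O4'", "C1'", "N")]))
    t2 = np.cos(np.deg2rad(A[("C2'", "C1'", "N")]))
    g = u1 @ u2
    a_ = (t1 - g * t2) / (1 - g * g)
    b_ = (t2 - g * t1) / (1 - g * g)
    c2_sq = 1.0 - (a_ * a_ + b_ * b_ + 2 * a_ * b_ * g)
    c_ = np.sqrt(max(c2_sq, 0.0))
    v = a_ * u1 + b_ * u2 + c_ * nrm
    if _beta_side(res, c1 + v) < 0:
        v = a_ * u1 + b_ * u2 - c_ * nrm
    n_glyco = c1 + B[("C1'", "N")] * v

    # realize the base plane through the chi torsion: place the chi partner
    # ring atom, then its in-plane sibling, and superpose the template
    partner = tmpl.chi_partner
    sibling = tmpl.frame_atoms[2]
    p2 = tmpl.atoms2d
    bond_p = np.linalg.norm(p2[partner] - p2[tmpl.glyco_atom])
    bond_s = np.linalg.norm(p2[sibling] - p2[tmpl.glyco_atom])

    def interior(at):
        u = -p2[tmpl.glyco_atom]
        w = p2[at] - p2[tmpl.glyco_atom]
        cosv = u @ w / (np.linalg.norm(u) * np.linalg.norm(w))
        return np.rad2deg(np.arccos(np.clip(cosv, -1, 1)))

    pos_partner = place_atom(res["O4'"], c1, n_glyco, bond_p, interior(partner), chi)
    pos_sibling = place_atom(res["O4'"], c1, n_glyco, bond_s, interior(sibling), chi + 180.0)
    tpl_pts = np.array([np.append(p2[n], 0.0) for n in (tmpl.glyco_atom, partner, sibling)])
    ref_pts = np.array([n_glyco, pos_partner, pos_sibling])
    rot, tr = kabsch(tpl_pts, ref_pts)
    for n, q in p2.items():
        if n == "C1'":
            continue
        res[n] = rot @ np.append(q, 0.0) + tr


# ---------------------------------------------------------------------------
# chain forward building
# ---------------------------------------------------------------------------


def build_from_torsions(
    sequence: str,
    nt_torsions: list[dict[str, float]],
    chis: list[float] | None = None,
) -> NucleotideModel:
    """Grow a chain from explicit per-nucleotide torsions.

    ``nt_torsions[i]`` needs keys alpha/beta/gamma/delta for every i (alpha,
    beta, gamma ignored for i=0 only in the sense that they orient the
    5'-terminal stub) and epsilon/zeta for i < n-1.
    """
    n = len(sequence)
    if len(nt_torsions) != n:
        raise ValueError("one torsion dict per nucleotide required")
    residues: list[dict[str, np.ndarray]] = []
    for i in range(n):
        t = nt_torsions[i]
        res: dict[str, np.ndarray] = {}
        if i == 0:
            res["P"] = np.zeros(3)
            res["O5'"] = np.array([B[("P", "O5'")], 0.0, 0.0])
            ang = np.deg2rad(180.0 - A[("P", "O5'", "C5'")])
            res["C5'"] = res["O5'"] + B[("O5'", "C5'")] * np.array(
                [np.cos(ang), np.sin(ang), 0.0]
            )
        else:
            prev = residues[i - 1]
            tp = nt_torsions[i - 1]
            res["P"] = place_atom(prev["C4'"], prev["C3'"], prev["O3'"],
                                  B[("O3'", "P")], A[("C3'", "O3'", "P")], tp["epsilon"])
            res["O5'"] = place_atom(prev["C3'"], prev["O3'"], res["P"],
                                     B[("P", "O5'")], A[("O3'", "P", "O5'")], tp["zeta"])
            res["C5'"] = place_atom(prev["O3'"], res["P"], res["O5'"],
                                     B[("O5'", "C5'")], A[("P", "O5'", "C5'")], t["alpha"])
        res["C4'"] = place_atom(res["P"], res["O5'"], res["C5'"],
                                 B[("C5'", "C4'")], A[("O5'", "C5'", "C4'")], t["beta"])
        res["C3'"] = place_atom(res["O5'"], res["C5'"], res["C4'"],
                                 B[("C4'", "C3'")], A[("C5'", "C4'", "C3'")], t["gamma"])
        res["O3'"] = place_atom(res["C5'"], res["C4'"], res["C3'"],
                                 B[("C3'", "O3'")], A[("C4'", "C3'", "O3'")], t["delta"])
        pucker = constants.pucker_from_delta(t["delta"])
        _complete_sugar(res, pucker)
        chi = (chis[i] if chis is not None else constants.DEFAULT_CHI[pucker])
        _attach_base(res, sequence[i], chi)
        residues.append(res)
    return NucleotideModel(residues=residues, sequence=sequence)


def _context_suite(pucker: str) -> ConformerDef:
    return load_library()[CONTEXT_SUITE_NAME[pucker]]


def assemble_nt_torsions(
    sequence: str, conformer_names: list[str]
) -> list[dict[str, float]]:
    """Distribute suite torsion means onto per-nucleotide torsions,
    checking shared-pucker consistency between adjacent suites."""
    lib = load_library()
    n = len(sequence)
    suites = [lib[c] for c in conformer_names]
    for a_, b_ in zip(suites, suites[1:]):
        if a_.ending_pucker != b_.leading_pucker:
            raise ValueError(
                f"pucker mismatch at junction {a_.name}->{b_.name}: "
                f"{a_.ending_pucker} vs {b_.leading_pucker}"
            )
    nts: list[dict[str, float]] = [{} for _ in range(n)]
    for i in range(n):
        if i == 0 and suites:
            nts[0]["delta"] = suites[0].torsions[0]
            ctx = _context_suite(suites[0].leading_pucker)
            nts[0]["alpha"], nts[0]["beta"], nts[0]["gamma"] = ctx.torsions[3:6]
        elif suites:
            nts[i]["delta"] = suites[i - 1].torsions[6]
            nts[i]["alpha"] = suites[i - 1].torsions[3]
            nts[i]["beta"] = suites[i - 1].torsions[4]
            nts[i]["gamma"] = suites[i - 1].torsions[5]
        else:  # single nucleotide, no suites
            ctx = _context_suite("C3'-endo")
            nts[i]["delta"] = ctx.torsions[0]
            nts[i]["alpha"], nts[i]["beta"], nts[i]["gamma"] = ctx.torsions[3:6]
        if i < n - 1:
            nts[i]["epsilon"] = suites[i].torsions[1]
            nts[i]["zeta"] = suites[i].torsions[2]
    return nts


def build_ideal_model(spec: SyntheticSpec, chis: list[float] | None = None) -> NucleotideModel:
    """Forward-build an all-atom model whose suites hit the conformer
    torsion means exactly."""
    names = spec.conformer_names()
    nts = assemble_nt_torsions(spec.sequence, names)
    model = build_from_torsions(spec.sequence, nts, chis=chis)
    model.conformers = names
    return model


# ---------------------------------------------------------------------------
# map simulation
# ---------------------------------------------------------------------------


def simulate_map(model: NucleotideModel, spec: SyntheticSpec) -> DensityGrid:
    """Gaussian-atom density for a model: width from the B-factor-like
    blur, amplitude from the atomic number, optional seeded white noise (in
    clean-map sigma units), then sigma-scaled on load."""
    if len(model) == 0:
        raise ValueError("empty model")
    coords = []
    weights = []
    for res in model.residues:
        for nm, pos in res.items():
            coords.append(pos)
            weights.append(constants.ELEMENT_WEIGHTS[constants.element_of(nm)])
    coords = np.array(coords)
    weights = np.array(weights)

    sigma_atom = float(np.sqrt(spec.blur_b / (8.0 * np.pi**2) + ATOM_SIGMA0**2))
    lo = coords.min(axis=0) - spec.pad
    hi = coords.max(axis=0) + spec.pad
    dims = np.ceil((hi - lo) / spec.voxel).astype(int) + 1
    values = np.zeros(dims)
    cut = 4.0 * sigma_atom
    ncut = int(np.ceil(cut / spec.voxel))
    axes = [np.arange(dims[k]) * spec.voxel + lo[k] for k in range(3)]
    for pos, w in zip(coords, weights):
        ijk = np.round((pos - lo) / spec.voxel).astype(int)
        sl = [slice(max(ijk[k] - ncut, 0), min(ijk[k] + ncut + 1, dims[k])) for k in range(3)]
        dx = axes[0][sl[0]] - pos[0]
        dy = axes[1][sl[1]] - pos[1]
        dz = axes[2][sl[2]] - pos[2]
        r2 = (
            dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        )
        values[tuple(sl)] += w * np.exp(-r2 / (2.0 * sigma_atom**2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd * values.std(), size=values.shape)
    return DensityGrid(origin=lo, voxel_spacing=np.full(3, float(spec.voxel)), values=values)


# ---------------------------------------------------------------------------
# classifier references and ensembles
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _reference_fragment(conformer_name: str) -> NucleotideModel:
    lib = load_library()
    conf = lib[conformer_name]
    ctx = _context_suite(conf.ending_pucker)
    return build_ideal_model(SyntheticSpec(sequence="AAA", conformers=(conf.name, ctx.name)))


def suite_anchor_reference(conf: ConformerDef | str) -> SuiteAnchors:
    """Noise-free anchor atoms of a conformer's suite, forward-built in a
    canonical flanking context.  Used as classifier centroids."""
    name = conf if isinstance(conf, str) else conf.name
    return _reference_fragment(name).suite_anchors(1)


def jitter_anchors(anchors: SuiteAnchors, sd: float, rng: np.random.Generator) -> SuiteAnchors:
    """Perturb each anchor atom with isotropic Gaussian noise of SD ``sd`` Å."""
    pts = anchors.chain() + rng.normal(0.0, sd, size=(5, 3))
    return SuiteAnchors(*pts)


def reference_models(
    seed: int = 2024,
    n_helices: int = 10,
    helix_len: int = 8,
    coord_noise: float = 0.25,
) -> list[NucleotideModel]:
    """Ideal-geometry ensemble for regenerating the likelihood curves:
    A-form helices with small Gaussian torsion jitter plus one forward-built
    fragment per library conformer.  ``coord_noise`` (Å) adds isotropic
    coordinate scatter so the curves carry the positional uncertainty of
    surveyed (and traced) coordinates rather than exact ideal geometry."""
    rng = np.random.default_rng(seed)
    lib = load_library()
    models = []
    bases = "ACGU"
    for h in range(n_helices):
        seq = "".join(bases[(h + k) % 4] for k in range(helix_len))
        nts = assemble_nt_torsions(seq, ["1a"] * (helix_len - 1))
        for i, t in enumerate(nts):
            for key in t:
                if key == "delta" and 0 < i:
                    continue  # keep shared deltas consistent
                t[key] = t[key] + rng.normal(0.0, 8.0)
        chis = []
        for i in range(helix_len):
            base_chi = 62.0 if rng.random() < 0.1 else constants.DEFAULT_CHI["C3'-endo"]
            chis.append(base_chi + rng.normal(0.0, 12.0))
        models.append(build_from_torsions(seq, nts, chis=chis))
    for k, conf in enumerate(lib):
        seq = "".join(bases[(k + j) % 4] for j in range(3))
        ctx = _context_suite(conf.ending_pucker)
        spec = SyntheticSpec(sequence=seq, conformers=(conf.name, ctx.name))
        chis = [
            constants.DEFAULT_CHI[constants.pucker_from_delta(t["delta"])]
            + rng.normal(0.0, 8.0)
            for t in assemble_nt_torsions(seq, list(spec.conformer_names()))
        ]
        models.append(build_ideal_model(spec, chis=chis))
    if coord_noise > 0:
        for m in models:
            for res in m.residues:
                for nm in res:
                    res[nm] = res[nm] + rng.normal(0.0, coord_noise, size=3)
    return models
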