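"""Coordinate frames and empirical regressions for RNA backbone tracing.

The tracing method locates the ribose sugar center G between a pair of
consecutive phosphates (P5', P3') using two empirical regressions in a
cylindrical coordinate system whose axis runs from P5' to P3':

* the radial offset ``r`` of G from the P5'->P3' axis is a quadratic
  function of the interphosphate distance ``d``;
* the height ``z`` of G along the axis is a linear function of ``d``.

The azimuth ``xi`` about the axis is not determined by geometry alone and is
chosen to maximize the electron density along the G->P5' and G->P3' vectors.
Once G is known, the C1' atom is placed at a fixed offset in a local
Cartesian frame built from G and the two phosphates.  The regression
coefficients and the C1' offset were fitted on a large curated set of RNA
crystal structures and are treated here as constants (config-overridable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegressionCoefficients",
    "PhosphatePair",
    "CylindricalFrame",
    "SugarCenter",
    "LocalSugarFrame",
    "torsion",
    "angle",
    "place_atom",
    "kabsch",
    "predict_rz",
    "place_sugar_center",
    "place_c1prime",
]

MAX_PP_DISTANCE = 10.0  # Å; phosphate pairs further apart are not traceable


@dataclass(frozen=True)
class RegressionCoefficients:
    """Empirical constants mapping interphosphate distance to sugar geometry.

    ``r(d) = a1*d**2 + a2*d + a3`` (Å), ``z(d) = b1*d + b2`` (Å), and
    ``c1p_offset`` is the mean C1' position in the local sugar frame.
    """

    a1: float = -0.186
    a2: float = 1.623
    a3: float = -0.124
    b1: float = 0.440
    b2: float = 0.910
    c1p_offset: tuple[float, float, float] = (-1.036, 0.202, -0.601)


@dataclass(frozen=True)
class PhosphatePair:
    """An ordered (5', 3') pair of phosphate positions."""

    p5: np.ndarray
    p3: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p5", np.asarray(self.p5, dtype=float))
        object.__setattr__(self, "p3", np.asarray(self.p3, dtype=float))
        if self.d <= 0.0:
            raise ValueError("coincident phosphates: d must be > 0")

    @property
    def d(self) -> float:
        return float(np.linalg.norm(self.p3 - self.p5))


@dataclass(frozen=True)
class CylindricalFrame:
    """Cylindrical system with origin at P5' and axis toward P3'.

    ``polar_ref`` is an arbitrary-but-deterministic unit vector orthogonal
    to the axis from which the azimuth xi is measured.
    """

    origin: np.ndarray
    axis: np.ndarray
    polar_ref: np.ndarray

    @classmethod
    def from_pair(cls, pair: PhosphatePair) -> "CylindricalFrame":
        axis = pair.p3 - pair.p5
        axis = axis / np.linalg.norm(axis)
        # deterministic perpendicular: cross with the least-aligned unit axis
        trial = np.eye(3)[np.argmin(np.abs(axis))]
        ref = np.cross(axis, trial)
        ref /= np.linalg.norm(ref)
        return cls(origin=np.asarray(pair.p5, dtype=float), axis=axis, polar_ref=ref)

    def to_cartesian(self, r: float, xi_deg: float, z: float) -> np.ndarray:
        xi = np.deg2rad(xi_deg)
        perp2 = np.cross(self.axis, self.polar_ref)
        return (
            self.origin
            + z * self.axis
            + r * (np.cos(xi) * self.polar_ref + np.sin(xi) * perp2)
        )

    def to_cylindrical(self, point: np.ndarray) -> tuple[float, float, float]:
        v = np.asarray(point, dtype=float) - self.origin
        z = float(v @ self.axis)
        radial = v - z * self.axis
        r = float(np.linalg.norm(radial))
        perp2 = np.cross(self.axis, self.polar_ref)
        xi = float(np.rad2deg(np.arctan2(radial @ perp2, radial @ self.polar_ref)))
        return r, xi % 360.0, z


@dataclass(frozen=True)
class SugarCenter:
    """A candidate ribose geometric center with its cylindrical coordinates."""

    position: np.ndarray
    r: float
    z: float
    xi: float
    frame: CylindricalFrame


@dataclass(frozen=True)
class LocalSugarFrame:
    """Orthonormal frame at the sugar center used to place C1'.

    x is the bisector of G->P5' and G->P3'; z is the normal of the
    P5'-G-P3' plane (normalized (G->P5') x (G->P3')); y lies in that plane
    completing the triad so that z = y x x.  This orientation reproduces
    the empirical mean C1' offset (-1.036, 0.202, -0.601) on ideal A-form
    geometry.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    @classmethod
    def from_points(cls, g: np.ndarray, p5: np.ndarray, p3: np.ndarray) -> "LocalSugarFrame":
        g = np.asarray(g, dtype=float)
        u5 = np.asarray(p5, dtype=float) - g
        u3 = np.asarray(p3, dtype=float) - g
        n5, n3 = np.linalg.norm(u5), np.linalg.norm(u3)
        if n5 < 1e-9 or n3 < 1e-9:
            raise ValueError("sugar center coincides with a phosphate")
        u5, u3 = u5 / n5, u3 / n3
        x = u5 + u3
        nx = np.linalg.norm(x)
        y = np.cross(u5, u3)
        ny = np.linalg.norm(y)
        if nx < 1e-9 or ny < 1e-9:
            raise ValueError("collinear P5'-G-P3': local frame undefined")
        x /= nx
        z = y / ny
        y = np.cross(x, z)
        return cls(origin=g, x_axis=x, y_axis=y, z_axis=z)

    def to_world(self, local: np.ndarray) -> np.ndarray:
        lx, ly, lz = np.asarray(local, dtype=float)
        return self.origin + lx * self.x_axis + ly * self.y_axis + lz * self.z_axis

    def to_local(self, world: np.ndarray) -> np.ndarray:
        v = np.asarray(world, dtype=float) - self.origin
        return np.array([v @ self.x_axis, v @ self.y_axis, v @ self.z_axis])


def torsion(p1, p2, p3, p4) -> float:
    """Dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180].

    Positive when, looking down p2->p3, the far bond p3->p4 is rotated
    clockwise from the near bond p2->p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear points: torsion undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.rad2deg(np.arctan2(m @ n2, n1 @ n2))
    return float(ang) if ang != -180.0 else 180.0


def angle(p1, p2, p3) -> float:
    """Bond angle at p2 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, ang_deg: float, tor_deg: float) -> np.ndarray:
    """Place atom d bonded to c with |d-c|=bond, angle(b,c,d)=ang and
    torsion(a,b,c,d)=tor (natural-extension/internal-coordinate placement)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.deg2rad(ang_deg)
    tor = np.deg2rad(tor_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in place_atom")
    n /= nn
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition: returns (R, t) with
    ``mobile @ R.T + t`` approximating ``target``."""
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, sign])
    r = vt.T @ dmat @ u.T
    t = ct - r @ cm
    return r, t


def predict_rz(d: float, coeffs: RegressionCoefficients | None = None) -> tuple[float, float]:
    """Predict the sugar-center cylindrical coordinates (r, z) from the
    interphosphate distance d (Å).  Valid for 0 < d <= 10 Å."""
    coeffs = coeffs or RegressionCoefficients()
    if not 0.0 < d <= MAX_PP_DISTANCE:
        raise ValueError(f"interphosphate distance {d:.3f} outside (0, {MAX_PP_DISTANCE}]")
    r = coeffs.a1 * d * d + coeffs.a2 * d + coeffs.a3
    z = coeffs.b1 * d + coeffs.b2
    return float(r), float(z)


def place_sugar_center(
    pair: PhosphatePair,
    grid,
    coeffs: RegressionCoefficients | None = None,
    n_samples: int = 10,
    scan_step_deg: float = 2.0,
) -> SugarCenter:
    """Locate the candidate sugar center G for a phosphate pair.

    r and z come from :func:`predict_rz`; the azimuth xi is scanned (then
    refined by golden-section search) to maximize the summed density along
    the G->P5' and G->P3' segments.  Ties break toward the smallest xi in
    [0, 360).
    """
    from .density import sample_segment_density  # local import to avoid cycle

    coeffs = coeffs or RegressionCoefficients()
    r, z = predict_rz(pair.d, coeffs)
    frame = CylindricalFrame.from_pair(pair)

    def objective(xi_deg: float) -> float:
        g = frame.to_cartesian(r, xi_deg, z)
        return sample_segment_density(grid, g, pair.p5, n_samples) + sample_segment_density(
            grid, g, pair.p3, n_samples
        )

    xis = np.arange(0.0, 360.0, scan_step_deg)
    vals = np.array([objective(x) for x in xis])
    best = int(np.argmax(vals))  # first maximizer wins on exact ties

    # golden-section refinement within one scan step either side
    lo, hi = xis[best] - scan_step_deg, xis[best] + scan_step_deg
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a_, b_ = lo, hi
    c_ = b_ - invphi * (b_ - a_)
    d_ = a_ + invphi * (b_ - a_)
    fc, fd = objective(c_), objective(d_)
    for _ in range(30):
        if fc >= fd:
            b_, d_, fd = d_, c_, fc
            c_ = b_ - invphi * (b_ - a_)
            fc = objective(c_)
        else:
            a_, c_, fc = c_, d_, fd
            d_ = a_ + invphi * (b_ - a_)
            fd = objective(d_)
    xi_ref = (c_ if fc >= fd else d_) % 360.0
    if max(fc, fd) < vals[best]:
        xi_ref = xis[best]
    return SugarCenter(
        position=frame.to_cartesian(r, xi_ref, z), r=r, z=z, xi=float(xi_ref), frame=frame
    )


def place_c1prime(
    center: SugarCenter | np.ndarray,
    pair: PhosphatePair,
    coeffs: RegressionCoefficients | None = None,
) -> np.ndarray:
    """Place the C1' atom at the empirical mean offset in the local sugar
    frame built from the sugar center G and the phosphate pair."""
    coeffs = coeffs or RegressionCoefficients()
    g = center.position if isinstance(center, SugarCenter) else np.asarray(center, dtype=float)
    frame = LocalSugarFrame.from_points(g, pair.p5, pair.p3)
    return frame.to_world(np.asarray(coeffs.c1p_offset))
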