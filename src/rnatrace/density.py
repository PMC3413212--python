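"""Electron-density map handling and the multi-contour phosphate peak search.

Maps are held on orthogonal-axis grids in absolute (Å) coordinates; values
are exposed in sigma units (map standard deviations above the mean), the
scale on which all contour thresholds and density scores operate.  Potential
phosphate sites are found by thresholding the map at a ladder of contour
levels (default 1σ..7σ in 0.25σ steps), splitting each thresholded map into
face-connected regions and keeping the highest-density grid point of every
region; the union over all levels is de-duplicated.  The search runs once
per map and is cached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "DensityGrid",
    "Peak",
    "PeakSet",
    "load_map",
    "save_map",
    "find_peaks",
    "peaks_near",
    "sample_segment_density",
    "DEFAULT_CONTOUR_LEVELS",
]

DEFAULT_CONTOUR_LEVELS = tuple(np.arange(1.0, 7.0 + 1e-9, 0.25))


@dataclass
class DensityGrid:
    """A 3-D density map on an orthogonal grid.

    ``values[i, j, k]`` is the raw density at Cartesian position
    ``origin + (i, j, k) * voxel_spacing``.
    """

    origin: np.ndarray
    voxel_spacing: np.ndarray
    values: np.ndarray
    mean: float = field(init=False)
    sigma: float = field(init=False)
    _peak_cache: dict = field(init=False, default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_spacing = np.asarray(self.voxel_spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("density grid must be 3-D with dims >= 2 on all axes")
        if np.any(self.voxel_spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")
        self.mean = float(self.values.mean())
        self.sigma = float(self.values.std())
        if self.sigma <= 0.0:
            raise ValueError("zero-variance map: sigma scaling undefined")

    # -- basic geometry -----------------------------------------------------

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def upper_corner(self) -> np.ndarray:
        return self.origin + (np.array(self.dims) - 1) * self.voxel_spacing

    def sigma_values(self) -> np.ndarray:
        if not hasattr(self, "_sigma_cache"):
            object.__setattr__(self, "_sigma_cache", (self.values - self.mean) / self.sigma)
        return self._sigma_cache

    def grid_position(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.voxel_spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((pts >= self.origin) & (pts <= self.upper_corner), axis=1)

    # -- interpolation ------------------------------------------------------

    def sample(self, points: np.ndarray, outside: str = "zero") -> np.ndarray:
        """Trilinear interpolation of the sigma-scaled map at Cartesian
        ``points`` (single triple or (n, 3) array).

        Points outside the grid contribute 0 when ``outside='zero'`` or
        raise when ``outside='raise'``.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        frac = (pts - self.origin) / self.voxel_spacing
        inside = np.all((frac >= 0) & (frac <= np.array(self.dims) - 1), axis=1)
        if outside == "raise" and not inside.all():
            raise ValueError("sample point outside grid")
        if not inside.all():
            log.debug("%d sample point(s) outside grid treated as 0", (~inside).sum())
        frac = np.clip(frac, 0.0, np.array(self.dims) - 1.000001)
        i0 = np.floor(frac).astype(int)
        i0 = np.minimum(i0, np.array(self.dims) - 2)
        t = frac - i0
        v = self.sigma_values()
        out = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (t[:, 0] if dx else 1 - t[:, 0])
                        * (t[:, 1] if dy else 1 - t[:, 1])
                        * (t[:, 2] if dz else 1 - t[:, 2])
                    )
                    out += w * v[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
        out[~inside] = 0.0
        if np.isscalar(points[0]) or np.asarray(points).ndim == 1:
            return float(out[0])
        return out

    def sample_with_gradient(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Trilinear sample of the sigma-scaled map and its spatial
        gradient (sigma units per Å) at (n, 3) Cartesian points; both are
        zero outside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        frac = (pts - self.origin) / self.voxel_spacing
        inside = np.all((frac >= 0) & (frac <= np.array(self.dims) - 1), axis=1)
        frac = np.clip(frac, 0.0, np.array(self.dims) - 1.000001)
        i0 = np.minimum(np.floor(frac).astype(int), np.array(self.dims) - 2)
        t = frac - i0
        v = self.sigma_values()
        vals = np.zeros(len(pts))
        grads = np.zeros((len(pts), 3))
        for dx in (0, 1):
            wx = t[:, 0] if dx else 1 - t[:, 0]
            gx = 1.0 if dx else -1.0
            for dy in (0, 1):
                wy = t[:, 1] if dy else 1 - t[:, 1]
                gy = 1.0 if dy else -1.0
                for dz in (0, 1):
                    wz = t[:, 2] if dz else 1 - t[:, 2]
                    gz = 1.0 if dz else -1.0
                    corner = v[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
                    vals += wx * wy * wz * corner
                    grads[:, 0] += gx * wy * wz * corner
                    grads[:, 1] += wx * gy * wz * corner
                    grads[:, 2] += wx * wy * gz * corner
        grads /= self.voxel_spacing[None, :]
        vals[~inside] = 0.0
        grads[~inside] = 0.0
        return vals, grads


@dataclass(frozen=True)
class Peak:
    """A candidate phosphate site: the highest-density grid point of a
    connected region at some contour level."""

    position: np.ndarray
    density_value: float  # sigma units
    source_contour: float  # sigma level that produced the region


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]
    dedup_radius: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def positions(self) -> np.ndarray:
        if not self.peaks:
            return np.zeros((0, 3))
        return np.array([p.position for p in self.peaks])


# ---------------------------------------------------------------------------
# map I/O (CCP4/MRC via gemmi)
# ---------------------------------------------------------------------------

def load_map(path: str) -> DensityGrid:
    """Read a CCP4/MRC volume.  Only orthogonal-axis maps are supported;
    the Cartesian origin is taken from the MRC ORIGIN header words."""
    import gemmi

    ccp4 = gemmi.read_ccp4_map(str(path))
    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90.0) < 1e-3
        and abs(cell.beta - 90.0) < 1e-3
        and abs(cell.gamma - 90.0) < 1e-3
    ):
        raise ValueError("non-orthogonal-axis maps are not supported")
    values = np.array(ccp4.grid, copy=True, dtype=float)
    nx, ny, nz = values.shape
    voxel = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin = np.array([ccp4.header_float(i) for i in (50, 51, 52)], dtype=float)
    return DensityGrid(origin=origin, voxel_spacing=voxel, values=values)


def save_map(grid: DensityGrid, path: str) -> None:
    """Write a DensityGrid as a CCP4/MRC mode-2 (float) map."""
    import gemmi

    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.dims
    vx, vy, vz = grid.voxel_spacing
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    for i, v in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(i, float(v))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# peak search
# ---------------------------------------------------------------------------

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-face connectivity


def find_peaks(
    grid: DensityGrid,
    contour_levels=DEFAULT_CONTOUR_LEVELS,
    dedup_radius: float | None = None,
) -> PeakSet:
    """Multi-contour connected-component peak search.

    For every contour level, voxels at or above the level are partitioned
    into face-connected components and the maximum-density voxel of each
    component becomes a peak.  The union over all levels is de-duplicated:
    among peaks closer than ``dedup_radius`` (default 0.75 x the smallest
    voxel spacing) only the densest survives.  Results are cached on the
    grid, keyed by the level ladder and radius.
    """
    levels = tuple(float(c) for c in contour_levels)
    if not levels:
        raise ValueError("contour_levels must be nonempty")
    if dedup_radius is None:
        dedup_radius = 0.75 * float(np.min(grid.voxel_spacing))
    key = (levels, float(dedup_radius))
    if key in grid._peak_cache:
        return grid._peak_cache[key]

    sig = grid.sigma_values()
    raw: list[tuple[float, float, tuple[int, int, int]]] = []
    seen: set[tuple[int, int, int]] = set()
    for level in sorted(levels):
        mask = sig >= level
        if not mask.any():
            continue
        labels, n = ndimage.label(mask, structure=_FACE_STRUCTURE)
        argmaxes = ndimage.maximum_position(sig, labels, index=range(1, n + 1))
        for ijk in argmaxes:
            ijk = tuple(int(v) for v in ijk)
            if ijk in seen:
                continue
            seen.add(ijk)
            raw.append((float(sig[ijk]), level, ijk))

    # densest first; ties broken by lower source contour then voxel index
    raw.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[Peak] = []
    kept_pos = np.zeros((0, 3))
    for value, level, ijk in raw:
        pos = grid.grid_position(ijk)
        if len(kept_pos) and np.any(
            np.linalg.norm(kept_pos - pos, axis=1) < dedup_radius
        ):
            continue
        kept.append(Peak(position=pos, density_value=value, source_contour=level))
        kept_pos = np.vstack([kept_pos, pos])

    result = PeakSet(peaks=tuple(kept), dedup_radius=float(dedup_radius))
    grid._peak_cache[key] = result
    return result


def peaks_near(peaks: PeakSet, center, radius: float = 10.0) -> list[Peak]:
    """Peaks within ``radius`` of ``center``, closest first."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    if not len(peaks):
        return []
    d = np.linalg.norm(peaks.positions() - center, axis=1)
    order = np.argsort(d, kind="stable")
    return [peaks.peaks[i] for i in order if d[i] <= radius]


def sample_segment_density(grid: DensityGrid, a, b, n: int = 10) -> float:
    """Sum of sigma-scaled trilinear samples at ``n`` evenly spaced points
    on the segment [a, b], endpoints included.  Points outside the grid
    contribute zero."""
    if n < 2:
        raise ValueError("need at least 2 sample points")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = a[None, :] * (1 - t) + b[None, :] * t
    return float(np.sum(grid.sample(pts)))
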