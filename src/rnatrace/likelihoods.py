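"""Kernel-smoothed likelihood curves for candidate scoring.

Four empirical distributions drive nucleotide tracing: the interphosphate
distance (s_dist), the P-P-P angle (s_angle_p), the C1'-P-C1' angle
(s_angle_s) and the pseudo-chi torsion prior used during base fitting.
Each is a Gaussian-kernel density estimate tabulated on a fixed grid and
evaluated by linear interpolation.  The pseudo-chi curve is periodic and is
clamped below by a floor value so that an unusual (e.g. syn) base rotation
is never excluded outright by a strong density fit.

The curves bundled with the original method were derived from a large
curated survey of RNA crystal structures; here they are regenerated from
ideal-geometry ensembles (forward-built conformer suites plus A-form
helices with small torsion jitter, fixed seed).  The JSON serialization is
documented so externally derived tables can be dropped in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import angle

__all__ = [
    "LikelihoodCurve",
    "build_curve",
    "eval_likelihood",
    "ReferenceCurves",
    "reference_curves",
    "default_curves",
]


@dataclass(frozen=True)
class LikelihoodCurve:
    """A tabulated 1-D density with optional periodicity and floor."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    floor: float = 0.0
    periodic: bool = False

    def eval(self, x) -> float | np.ndarray:
        v = np.interp(
            np.mod(np.asarray(x, dtype=float) + 180.0, 360.0) - 180.0 if self.periodic else x,
            self.grid,
            self.density,
            left=self.floor,
            right=self.floor,
        )
        out = np.maximum(v, self.floor)
        return float(out) if np.ndim(x) == 0 else out

    def eval_ratio(self, x) -> float | np.ndarray:
        """Likelihood-ratio evaluation: the curve value scaled by its
        maximum, in [0, 1].  Puts curves of different dimensions (Å,
        degrees) on a common scale for weighted scoring."""
        peak = float(self.density.max())
        return self.eval(x) / peak if peak > 0 else self.eval(x)

    @property
    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.density))])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "density": self.density.tolist(),
            "bandwidth": self.bandwidth,
            "floor": self.floor,
            "periodic": self.periodic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LikelihoodCurve":
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            density=np.asarray(d["density"], dtype=float),
            bandwidth=float(d["bandwidth"]),
            floor=float(d.get("floor", 0.0)),
            periodic=bool(d.get("periodic", False)),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "LikelihoodCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _silverman(samples: np.ndarray) -> float:
    n = len(samples)
    sd = samples.std(ddof=1)
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return float(0.9 * spread * n ** (-0.2)) if spread > 0 else 1.0


def build_curve(
    samples,
    bandwidth: float | None = None,
    floor_frac: float = 0.0,
    periodic: bool = False,
    domain: tuple[float, float] | None = None,
    n_grid: int = 512,
) -> LikelihoodCurve:
    """Gaussian KDE of ``samples`` tabulated on a fixed grid.

    Bandwidth defaults to Silverman's rule.  Periodic (angular) curves wrap
    contributions at +-180 deg.  ``floor_frac`` sets the floor as a
    fraction of the curve maximum (0 disables the floor).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples")
    if samples.size < 10:
        raise ValueError("need at least 10 samples for a stable curve")
    h = bandwidth if bandwidth is not None else _silverman(samples)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if periodic:
        lo, hi = -180.0, 180.0
        reps = np.concatenate([samples - 360.0, samples, samples + 360.0])
    else:
        lo, hi = domain if domain else (samples.min() - 3 * h, samples.max() + 3 * h)
        reps = samples
    grid = np.linspace(lo, hi, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - reps[None, :]) / h) ** 2).sum(axis=1)
    dens /= samples.size * h * np.sqrt(2.0 * np.pi)
    floor = float(floor_frac * dens.max())
    return LikelihoodCurve(grid=grid, density=dens, bandwidth=float(h), floor=floor, periodic=periodic)


def eval_likelihood(curve: LikelihoodCurve, x) -> float | np.ndarray:
    """Evaluate a curve (linear interpolation, clamped below by its floor;
    outside the tabulated domain the floor is returned)."""
    return curve.eval(x)


@dataclass(frozen=True)
class ReferenceCurves:
    """The four tracing/scoring curves."""

    dist: LikelihoodCurve       # successive P-P distance (Å)
    angle_p: LikelihoodCurve    # P-P-P angle (deg, [0, 180])
    angle_s: LikelihoodCurve    # C1'-P-C1' angle (deg, [0, 180])
    pseudo_chi: LikelihoodCurve  # periodic, floored

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k).to_dict() for k in
                       ("dist", "angle_p", "angle_s", "pseudo_chi")}, fh)

    @classmethod
    def load(cls, path: str) -> "ReferenceCurves":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: LikelihoodCurve.from_dict(v) for k, v in d.items()})


def reference_curves(models, floor_frac_chi: float = 0.01) -> ReferenceCurves:
    """Build the four scoring curves from an ensemble of ideal-geometry
    models (see :func:`rnatrace.fixtures.reference_models`)."""
    models = list(models)
    dists, angs_p, angs_s, pchis = [], [], [], []
    for m in models:
        n = len(m)
        p = [m.atom(i, "P") for i in range(n)]
        c1 = [m.atom(i, "C1'") for i in range(n)]
        for i in range(n - 1):
            dists.append(float(np.linalg.norm(p[i + 1] - p[i])))
        for i in range(1, n - 1):
            angs_p.append(angle(p[i - 1], p[i], p[i + 1]))
            angs_s.append(angle(c1[i - 1], p[i], c1[i]))
        for i in range(n):
            try:
                pchis.append(m.pseudo_chi(i))
            except (KeyError, ValueError):
                continue
    if len(dists) < 10:
        raise ValueError("ensemble too small to derive curves")
    return ReferenceCurves(
        dist=build_curve(dists),
        angle_p=build_curve(angs_p, domain=(0.0, 180.0)),
        angle_s=build_curve(angs_s, domain=(0.0, 180.0)),
        pseudo_chi=build_curve(pchis, periodic=True, floor_frac=floor_frac_chi),
    )


@lru_cache(maxsize=4)
def default_curves(seed: int = 2024) -> ReferenceCurves:
    """Curves regenerated from the bundled ideal-geometry ensemble."""
    from .fixtures import reference_models

    return reference_curves(reference_models(seed=seed))
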