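"""Shared test utilities: oracle implementations and fixture adapters."""

from __future__ import annotations

import numpy as np

from rnatrace.bases import PROBE_LENGTH, PlacedBase, fit_base
from rnatrace.density import DensityGrid
from rnatrace.tracing import Trace, TraceAnchor


def trace_from_model(model, with_bases: bool = True) -> Trace:
    """Turn a fixture model into the trace the builder would receive."""
    anchors = []
    for i in range(len(model)):
        base = None
        if with_bases:
            base = PlacedBase(
                base_type=model.sequence[i],
                atoms={n: model.residues[i][n].copy() for n in model.base_atom_names(i)},
                c1p=model.atom(i, "C1'").copy(),
                p=model.atom(i, "P").copy(),
            )
        anchors.append(
            TraceAnchor(
                phosphate=model.atom(i, "P").copy(),
                c1p=model.atom(i, "C1'").copy(),
                base=base,
            )
        )
    return Trace(direction="5to3", anchors=tuple(anchors))


def fit_base_at(model, i, curves, grid) -> PlacedBase:
    """Rotationally fit the generic pyrimidine at residue i's true anchors."""
    c1p = model.atom(i, "C1'")
    p = model.atom(i, "P")
    mid = (model.residues[i]["C4"] + model.residues[i]["C5"]) / 2
    b_end = c1p + PROBE_LENGTH * (mid - c1p) / np.linalg.norm(mid - c1p)
    return fit_base(b_end, c1p, p, grid, chi_curve=curves.pseudo_chi)


def gaussian_blob_grid(n=32, centers=((8.0, 8.0, 8.0),), widths=(2.0,), voxel=0.5) -> DensityGrid:
    ax = np.arange(n) * voxel
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = np.zeros((n, n, n))
    for (cx, cy, cz), w in zip(centers, widths):
        vals += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2 * w**2))
    return DensityGrid(origin=np.zeros(3), voxel_spacing=np.full(3, voxel), values=vals)


def flood_fill_peaks(sig: np.ndarray, level: float) -> set:
    """Brute-force 6-neighbour flood-fill labeling; returns the max-density
    voxel index of every connected region at one contour level."""
    mask = sig >= level
    seen = np.zeros_like(mask, dtype=bool)
    peaks = set()
    dims = sig.shape
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        component = []
        while stack:
            ijk = stack.pop()
            component.append(ijk)
            for d in range(3):
                for step in (-1, 1):
                    nb = list(ijk)
                    nb[d] += step
                    nb = tuple(nb)
                    if 0 <= nb[d] < dims[d] and mask[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
        peaks.add(max(component, key=lambda c: sig[c]))
    return peaks
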