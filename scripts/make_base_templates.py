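"""Regenerate the bundled ideal nucleobase templates.

Each base is constructed as a planar 2D model satisfying standard bond
lengths and ring angles (least-squares closure), then stored in a canonical
in-plane frame: the glycosidic C1' at the origin and the glycosidic nitrogen
on the +x axis.  Run from the repository root:

    python scripts/make_base_templates.py
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
from scipy.optimize import least_squares

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "rnatrace" / "data" / "base_templates.json"

# name -> (bonds, angles, ring_atoms, glyco, frame_atoms, chi_partner, pseudo_chi_ref)
BASES = {
    "A": {
        "bonds": [("N1", "C2", 1.339), ("C2", "N3", 1.331), ("N3", "C4", 1.344),
                  ("C4", "C5", 1.383), ("C5", "C6", 1.406), ("C6", "N1", 1.351),
                  ("C4", "N9", 1.374), ("N9", "C8", 1.371), ("C8", "N7", 1.311),
                  ("N7", "C5", 1.388), ("C6", "N6", 1.335), ("N9", "C1'", 1.459)],
        "angles": [("C6", "N1", "C2", 118.6), ("N1", "C2", "N3", 129.3),
                   ("C2", "N3", "C4", 110.6), ("N3", "C4", "C5", 126.8),
                   ("C4", "C5", "C6", 117.0), ("C5", "C6", "N1", 117.7),
                   ("C4", "N9", "C8", 105.8), ("N9", "C8", "N7", 113.8),
                   ("C8", "N7", "C5", 103.9), ("N7", "C5", "C4", 110.7),
                   ("C5", "C4", "N9", 105.8), ("N1", "C6", "N6", 118.6),
                   ("C5", "C6", "N6", 123.7), ("C4", "N9", "C1'", 126.5),
                   ("C8", "N9", "C1'", 127.7)],
        "ring_atoms": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
        "glyco": "N9", "frame": ["N9", "C4", "C8"], "chi_partner": "C4",
        "pseudo_chi": ["N9", "N1"],
    },
    "G": {
        "bonds": [("N1", "C2", 1.373), ("C2", "N3", 1.323), ("N3", "C4", 1.350),
                  ("C4", "C5", 1.379), ("C5", "C6", 1.419), ("C6", "N1", 1.391),
                  ("C4", "N9", 1.375), ("N9", "C8", 1.374), ("C8", "N7", 1.305),
                  ("N7", "C5", 1.388), ("C6", "O6", 1.237), ("C2", "N2", 1.341),
                  ("N9", "C1'", 1.459)],
        "angles": [("C6", "N1", "C2", 125.1), ("N1", "C2", "N3", 123.9),
                   ("C2", "N3", "C4", 111.9), ("N3", "C4", "C5", 128.6),
                   ("C4", "C5", "C6", 118.8), ("C5", "C6", "N1", 111.5),
                   ("C4", "N9", "C8", 106.4), ("N9", "C8", "N7", 113.1),
                   ("C8", "N7", "C5", 104.3), ("N7", "C5", "C4", 110.8),
                   ("C5", "C4", "N9", 105.4), ("N1", "C6", "O6", 119.9),
                   ("C5", "C6", "O6", 128.6), ("N1", "C2", "N2", 116.1),
                   ("N3", "C2", "N2", 120.0), ("C4", "N9", "C1'", 126.5),
                   ("C8", "N9", "C1'", 127.1)],
        "ring_atoms": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
        "glyco": "N9", "frame": ["N9", "C4", "C8"], "chi_partner": "C4",
        "pseudo_chi": ["N9", "N1"],
    },
    "C": {
        "bonds": [("N1", "C2", 1.397), ("C2", "N3", 1.353), ("N3", "C4", 1.335),
                  ("C4", "C5", 1.425), ("C5", "C6", 1.339), ("C6", "N1", 1.367),
                  ("C2", "O2", 1.240), ("C4", "N4", 1.335), ("N1", "C1'", 1.473)],
        "angles": [("C6", "N1", "C2", 120.3), ("N1", "C2", "N3", 118.9),
                   ("C2", "N3", "C4", 120.0), ("N3", "C4", "C5", 121.9),
                   ("C4", "C5", "C6", 117.4), ("C5", "C6", "N1", 121.0),
                   ("N1", "C2", "O2", 118.9), ("N3", "C2", "O2", 122.2),
                   ("N3", "C4", "N4", 118.0), ("C5", "C4", "N4", 120.1),
                   ("C2", "N1", "C1'", 118.3), ("C6", "N1", "C1'", 121.4)],
        "ring_atoms": ["N1", "C2", "N3", "C4", "C5", "C6"],
        "glyco": "N1", "frame": ["N1", "C2", "C6"], "chi_partner": "C2",
        "pseudo_chi": ["N1", "N3"],
    },
    "U": {
        "bonds": [("N1", "C2", 1.381), ("C2", "N3", 1.373), ("N3", "C4", 1.380),
                  ("C4", "C5", 1.431), ("C5", "C6", 1.337), ("C6", "N1", 1.375),
                  ("C2", "O2", 1.219), ("C4", "O4", 1.232), ("N1", "C1'", 1.473)],
        "angles": [("C6", "N1", "C2", 121.0), ("N1", "C2", "N3", 114.9),
                   ("C2", "N3", "C4", 127.0), ("N3", "C4", "C5", 114.6),
                   ("C4", "C5", "C6", 119.7), ("C5", "C6", "N1", 122.7),
                   ("N1", "C2", "O2", 122.8), ("N3", "C2", "O2", 122.3),
                   ("N3", "C4", "O4", 119.4), ("C5", "C4", "O4", 126.0),
                   ("C2", "N1", "C1'", 117.7), ("C6", "N1", "C1'", 121.3)],
        "ring_atoms": ["N1", "C2", "N3", "C4", "C5", "C6"],
        "glyco": "N1", "frame": ["N1", "C2", "C6"], "chi_partner": "C2",
        "pseudo_chi": ["N1", "N3"],
    },
}


def initial_guess(spec):
    """Rough planar starting coordinates: regular hexagon, fused pentagon,
    substituents on radial rays."""
    coords = {}
    hexagon = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for i, name in enumerate(hexagon):
        ang = np.deg2rad(60.0 * i)
        coords[name] = 1.39 * np.array([np.cos(ang), np.sin(ang)])
    if "N9" in spec["ring_atoms"]:
        # regular pentagon fused on the C4-C5 edge, pointing away from ring center
        c4, c5 = coords["C4"], coords["C5"]
        mid = (c4 + c5) / 2.0
        out = mid / np.linalg.norm(mid)
        side = np.linalg.norm(c4 - c5)
        center = mid + out * side / (2.0 * np.tan(np.deg2rad(36.0)))
        radius = side / (2.0 * np.sin(np.deg2rad(36.0)))
        th4 = np.arctan2(*(c4 - center)[::-1])
        th5 = np.arctan2(*(c5 - center)[::-1])
        step = np.deg2rad(72.0) * np.sign((th4 - th5 + np.pi) % (2 * np.pi) - np.pi)
        for k, name in enumerate(("N9", "C8", "N7"), start=1):
            th = th4 + k * step
            coords[name] = center + radius * np.array([np.cos(th), np.sin(th)])
    ring = set(spec["ring_atoms"])
    for a, b, length in spec["bonds"]:
        for host, sub in ((a, b), (b, a)):
            if host in ring and sub not in ring and sub not in coords:
                ray = coords[host] / np.linalg.norm(coords[host])
                if host == "N9":
                    ray = (coords[host] - (coords["C4"] + coords["C8"]) / 2.0)
                    ray /= np.linalg.norm(ray)
                coords[sub] = coords[host] + length * ray
    return coords


def solve(spec):
    names = sorted({n for b in spec["bonds"] for n in b[:2]})
    init = initial_guess(spec)
    x0 = np.concatenate([init[n] for n in names])
    idx = {n: i for i, n in enumerate(names)}

    def residuals(x):
        pts = x.reshape(-1, 2)
        res = []
        for a, b, l0 in spec["bonds"]:
            res.append(10.0 * (np.linalg.norm(pts[idx[a]] - pts[idx[b]]) - l0))
        for a, b, c, th0 in spec["angles"]:
            u = pts[idx[a]] - pts[idx[b]]
            v = pts[idx[c]] - pts[idx[b]]
            cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            res.append(3.0 * (np.arccos(np.clip(cosv, -1, 1)) - np.deg2rad(th0)))
        return np.array(res)

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15)
    pts = sol.x.reshape(-1, 2)
    coords = {n: pts[idx[n]] for n in names}

    # canonical frame: C1' at origin, glyco N on +x, chi partner at +y side
    origin = coords["C1'"]
    xax = coords[spec["glyco"]] - origin
    xax /= np.linalg.norm(xax)
    yax = np.array([-xax[1], xax[0]])
    out = {n: np.array([(p - origin) @ xax, (p - origin) @ yax]) for n, p in coords.items()}
    if out[spec["chi_partner"]][1] < 0:
        out = {n: p * np.array([1.0, -1.0]) for n, p in out.items()}
    return out, float(np.abs(sol.fun).max())


def main():
    data = {"version": 1, "bases": {}}
    for name, spec in BASES.items():
        coords, worst = solve(spec)
        print(f"{name}: worst residual {worst:.2e}")
        data["bases"][name] = {
            "atoms": {n: [round(float(v), 6) for v in p] for n, p in coords.items()},
            "ring_atoms": spec["ring_atoms"],
            "glyco_atom": spec["glyco"],
            "frame_atoms": spec["frame"],
            "chi_partner": spec["chi_partner"],
            "pseudo_chi_base_atoms": spec["pseudo_chi"],
            "c4c5_bond": ["C4", "C5"],
        }
    OUT.write_text(json.dumps(data, indent=1))
    print("wrote", OUT)


if __name__ == "__main__":
    main()
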