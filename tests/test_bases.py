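"""Base templates, probe placement, rotational fit, mutation and flips."""

import numpy as np
import pytest

from rnatrace.bases import (
    PROBE_LENGTH,
    base_rmsd,
    fit_base,
    flip_base,
    load_templates,
    mutate_base,
    place_base_vector,
    refine_orientation,
)
from rnatrace.density import DensityGrid
from rnatrace.geometry import PhosphatePair, angle
from helpers import fit_base_at


def constant_grid(value=1.0, n=48, voxel=0.5):
    vals = np.full((n, n, n), value)
    vals[0, 0, 0] = value - 1.0  # nonzero variance
    return DensityGrid(origin=np.full(3, -n * voxel / 2), voxel_spacing=np.full(3, voxel), values=vals)


class TestTemplates:
    @pytest.mark.parametrize("base", ["A", "C", "G", "U"])
    def test_rings_planar_and_bonds_sane(self, base):
        t = load_templates()[base]
        ring = np.array([np.append(t.atoms2d[n], 0.0) for n in t.ring_atoms])
        # template is 2D so planarity is exact; check ring bond lengths
        for a, b in zip(t.ring_atoms, t.ring_atoms[1:] + (t.ring_atoms[0],)):
            d = np.linalg.norm(t.atoms2d[a] - t.atoms2d[b])
            if base in "AG" and {a, b} == {"N9", "N1"}:
                continue  # purine ring closure is through C4, not N9-N1
            if 1.28 <= d <= 1.47:
                continue
            # non-adjacent pair in the fused-ring traversal
            assert d > 1.47

    def test_glycosidic_and_pseudo_chi_atoms(self):
        t = load_templates()
        assert t["A"].glyco_atom == "N9" and t["G"].glyco_atom == "N9"
        assert t["C"].glyco_atom == "N1" and t["U"].glyco_atom == "N1"
        assert t["A"].pseudo_chi_base_atoms == ("N9", "N1")
        assert t["U"].pseudo_chi_base_atoms == ("N1", "N3")


class TestProbeVector:
    def test_probe_length_and_angle_constraint(self, helix7):
        _, model, grid, _ = helix7
        for i in range(1, 5):
            c1p = model.atom(i, "C1'")
            pair = PhosphatePair(p5=model.atom(i, "P"), p3=model.atom(i + 1, "P"))
            b_end = place_base_vector(c1p, pair, grid)
            assert np.linalg.norm(b_end - c1p) == pytest.approx(PROBE_LENGTH, abs=1e-6)
            bis = (pair.p5 - c1p) / np.linalg.norm(pair.p5 - c1p) + (
                pair.p3 - c1p
            ) / np.linalg.norm(pair.p3 - c1p)
            a = angle(c1p + bis, c1p, b_end)
            assert 90.0 - 1e-6 <= a <= 180.0 + 1e-6

    def test_probe_points_toward_true_base(self, helix7):
        _, model, grid, _ = helix7
        i = 2
        c1p = model.atom(i, "C1'")
        pair = PhosphatePair(p5=model.atom(i, "P"), p3=model.atom(i + 1, "P"))
        b_end = place_base_vector(c1p, pair, grid)
        mid = (model.residues[i]["C4"] + model.residues[i]["C5"]) / 2
        u = (b_end - c1p) / PROBE_LENGTH
        v = (mid - c1p) / np.linalg.norm(mid - c1p)
        assert np.degrees(np.arccos(np.clip(u @ v, -1, 1))) < 15.0


class TestFitBase:
    def test_uniform_density_decided_by_pseudo_chi_prior(self, curves):
        grid = constant_grid()
        c1p = np.array([0.0, 0.0, 0.0])
        p = np.array([-4.0, 3.0, 1.0])
        b_end = np.array([5.0, 0.0, 0.0])
        placed = fit_base(b_end, c1p, p, grid, chi_curve=curves.pseudo_chi)
        # with flat density the spin must sit at (or near) the prior mode
        chi_opt = placed.pseudo_chi()
        dens = [curves.pseudo_chi.eval(x) for x in np.arange(-180, 180, 1.0)]
        assert curves.pseudo_chi.eval(chi_opt) >= 0.95 * max(dens)

    def test_scan_matches_fine_grid_oracle(self, helix7, curves):
        _, model, grid, _ = helix7
        i = 3
        c1p = model.atom(i, "C1'")
        p = model.atom(i, "P")
        mid = (model.residues[i]["C4"] + model.residues[i]["C5"]) / 2
        b_end = c1p + PROBE_LENGTH * (mid - c1p) / np.linalg.norm(mid - c1p)
        placed = fit_base(b_end, c1p, p, grid, chi_curve=curves.pseudo_chi, scan_step_deg=5.0)
        fine = fit_base(b_end, c1p, p, grid, chi_curve=curves.pseudo_chi, scan_step_deg=1.0)
        s_placed = placed.s_ring_density + placed.s_pseudo_chi
        s_fine = fine.s_ring_density + fine.s_pseudo_chi
        assert s_placed >= s_fine - 0.05 * abs(s_fine)


class TestMutation:

    def test_c_to_u_keeps_ring_atoms(self, helix7, curves):
        _, model, grid, _ = helix7
        placed = fit_base_at(model, 1, curves, grid)  # C fit
        mutated = mutate_base(placed, "U")
        for nm in ("N1", "C2", "N3", "C4", "C5", "C6"):
            assert np.allclose(mutated.atoms[nm], placed.atoms[nm], atol=1e-12)
        assert "O4" in mutated.atoms and "N4" not in mutated.atoms

    def test_u_to_a_roundtrip_ring_rmsd(self, helix7, curves):
        _, model, grid, _ = helix7
        placed = fit_base_at(model, 1, curves, grid)
        mutated = mutate_base(mutate_base(placed, "A"), "C")
        rms = base_rmsd(mutated.atoms, placed.atoms,
                        names=["N1", "C2", "N3", "C4", "C5", "C6"])
        assert rms < 0.1

    def test_c_to_g_aligns_purine_c4c5_midpoint(self, helix7, curves):
        _, model, grid, _ = helix7
        placed = fit_base_at(model, 1, curves, grid)
        target_dir = placed.atoms["C4"] - placed.c1p
        target_dir /= np.linalg.norm(target_dir)
        g = mutate_base(placed, "G")
        mid = g.c4c5_mid()
        v = mid - g.c1p
        off_axis = np.linalg.norm(v - (v @ target_dir) * target_dir)
        assert off_axis < 0.2

    def test_unknown_base_rejected(self, helix7, curves):
        _, model, grid, _ = helix7
        placed = fit_base_at(model, 1, curves, grid)
        with pytest.raises(ValueError):
            mutate_base(placed, "X")


class TestFlip:
    def test_double_flip_is_identity(self, helix7, curves):
        _, model, grid, _ = helix7
        for i in (1, 2):  # a pyrimidine and a purine fit
            placed = fit_base_at(model, i, curves, grid)
            if i == 2:
                placed = mutate_base(placed, "G")
            back = flip_base(flip_base(placed))
            for nm in placed.atoms:
                assert np.allclose(back.atoms[nm], placed.atoms[nm], atol=1e-9)

    def test_pyrimidine_flip_fixes_axis_points(self, helix7, curves):
        _, model, grid, _ = helix7
        placed = fit_base_at(model, 1, curves, grid)
        flipped = flip_base(placed)
        assert np.allclose(flipped.c1p, placed.c1p, atol=1e-12)
        assert np.allclose(flipped.c4c5_mid(), placed.c4c5_mid(), atol=1e-9)

    def test_purine_flip_is_about_the_glycosidic_axis(self, helix7, curves):
        _, model, grid, _ = helix7
        placed = mutate_base(fit_base_at(model, 1, curves, grid), "A")
        flipped = flip_base(placed)
        # axis points (C1' and N9) stay put; off-axis atoms move
        assert np.allclose(flipped.atoms["N9"], placed.atoms["N9"], atol=1e-9)
        assert np.linalg.norm(flipped.atoms["N1"] - placed.atoms["N1"]) > 1.0

    def test_operations_are_rigid(self, helix7, curves):
        _, model, grid, _ = helix7
        placed = fit_base_at(model, 1, curves, grid)
        names = list(placed.atoms)
        ref = np.array([np.linalg.norm(placed.atoms[a] - placed.atoms[b])
                        for a in names for b in names])
        for variant in (flip_base(placed), refine_orientation(placed, grid)):
            got = np.array([np.linalg.norm(variant.atoms[a] - variant.atoms[b])
                            for a in names for b in names])
            assert np.allclose(got, ref, atol=1e-9)
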