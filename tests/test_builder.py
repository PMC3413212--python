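"""Restrained minimization: building, rotamerization, pucker targets."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rnatrace import constants
from rnatrace.builder import (
    RestraintSet,
    build_suites,
    pucker_targets,
    rebuild_with_conformer,
    rotamerize,
    suite_residual,
)
from rnatrace.conformers import load_library
from rnatrace.fixtures import _complete_sugar
from helpers import trace_from_model


@pytest.fixture(scope="module")
def mixed_built(mixed7):
    spec, model, grid, _ = mixed7
    tr = trace_from_model(model)
    built = build_suites(tr, predictions=list(spec.conformer_names()), grid=grid)
    return spec, model, grid, built


class TestPuckerTargets:
    def test_two_puckers_differ_and_lookup_is_stable(self):
        a = pucker_targets("C3'-endo")
        b = pucker_targets("C2'-endo")
        assert a != b
        assert pucker_targets("C3'-endo") == a

    def test_targets_reproduce_labelled_pucker(self):
        for pucker in ("C3'-endo", "C2'-endo"):
            nus = constants.nu_targets(pucker)
            phase = constants.pseudorotation_phase(nus)
            assert constants.pucker_from_phase(phase) == pucker

    def test_unknown_pucker_rejected(self):
        with pytest.raises(ValueError):
            pucker_targets("C1'-exo")


class TestRestraintEngine:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(17)
        n = 8
        x = rng.normal(size=3 * n) * 2
        rs = RestraintSet(n_atoms=n)
        rs.bonds = [(0, 1, 1.5, 12.0), (2, 3, 1.4, 5.0)]
        rs.angles = [(0, 1, 2, 109.0, 7.0), (3, 4, 5, 120.0, 3.0)]
        rs.torsions = [(0, 1, 2, 3, -65.0, 4.0), (2, 3, 4, 5, 170.0, 8.0)]
        rs.positions = [(6, np.array([1.0, 0.0, 2.0]), 2.5)]
        _, g = rs.energy_and_grad(x)
        num = np.zeros_like(x)
        h = 1e-6
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[i] = (rs.energy_and_grad(xp)[0] - rs.energy_and_grad(xm)[0]) / (2 * h)
        assert np.abs(g - num).max() < 1e-6

    def test_minimization_reduces_objective(self, mixed7):
        spec, model, grid, _ = mixed7
        tr = trace_from_model(model)
        built = build_suites(tr, predictions=list(spec.conformer_names()), grid=grid)
        assert built.suite_residuals is not None


class TestBuildSuites:
    def test_ideal_a_form_anchors_rebuilt_to_mean_torsions(self, helix7):
        _, model, _, _ = helix7
        tr = trace_from_model(model)
        built = build_suites(tr, predictions=["1a"] * 6, grid=None)
        lib = load_library()
        for j in range(1, 7):
            dev = (built.suite_torsions(j) - np.array(lib["1a"].torsions) + 180) % 360 - 180
            assert np.abs(dev).max() < 5.0

    def test_phosphates_stay_on_their_anchors(self, mixed_built):
        _, model, _, built = mixed_built
        for i in range(len(built)):
            assert np.linalg.norm(built.atom(i, "P") - model.atom(i, "P")) < 0.3

    def test_chain_connectivity_bonds(self, mixed_built):
        _, _, _, built = mixed_built
        for i in range(len(built) - 1):
            d = np.linalg.norm(built.atom(i, "O3'") - built.atom(i + 1, "P"))
            assert 1.4 <= d <= 1.8

    def test_build_residuals_small_on_clean_fixture(self, mixed_built):
        _, _, _, built = mixed_built
        assert max(built.suite_residuals) < 20.0

    def test_density_term_improves_map_fit(self, mixed7):
        spec, model, grid, _ = mixed7
        tr = trace_from_model(model)
        with_d = build_suites(tr, predictions=list(spec.conformer_names()), grid=grid)
        without = build_suites(tr, predictions=list(spec.conformer_names()), grid=None)

        def mean_density(m):
            pts = np.array([xyz for res in m.residues for xyz in res.values()])
            return float(np.mean(grid.sample(pts)))

        assert mean_density(with_d) >= mean_density(without) - 1e-6

    def test_prediction_path_recovers_a_form(self, helix7, classifier):
        _, model, _, _ = helix7
        tr = trace_from_model(model)
        built = build_suites(tr, grid=None, classifier=classifier)
        assert built.conformers.count("1a") >= 4

    def test_rigid_motion_equivariance(self, mixed7):
        spec, model, _, _ = mixed7
        tr = trace_from_model(model)
        built = build_suites(tr, predictions=list(spec.conformer_names()), grid=None)
        rot = Rotation.random(random_state=4).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        moved = model.transformed(rot, shift)
        tr2 = trace_from_model(moved)
        built2 = build_suites(tr2, predictions=list(spec.conformer_names()), grid=None)
        for i in (0, 3, 6):
            for nm in ("P", "C1'", "O3'"):
                expect = rot @ built.atom(i, nm) + shift
                assert np.linalg.norm(built2.atom(i, nm) - expect) < 5e-3


class TestRotamerize:
    def test_ideal_stretch_is_idempotent(self, helix7):
        _, model, grid, _ = helix7
        out = rotamerize(model.copy(), 2, 4, grid=grid)
        deltas = [
            np.linalg.norm(out.residues[i][nm] - model.residues[i][nm])
            for i in range(len(model))
            for nm in model.residues[i]
        ]
        assert np.sqrt(np.mean(np.square(deltas))) < 0.2
        for j in range(2, 5):
            assert out.conformers[j - 1] == "1a"

    def test_wrong_pucker_is_repaired(self, helix7):
        _, model, grid, _ = helix7
        bad = model.copy()
        bad.conformers = list(model.conformers)
        _complete_sugar(bad.residues[3], "C2'-endo")
        assert bad.pucker(3) == "C2'-endo"
        fixed = rotamerize(bad, 3, 3, grid=grid)
        assert fixed.pucker(3) == "C3'-endo"

    def test_atoms_outside_span_unchanged_bitwise(self, helix7):
        _, model, grid, _ = helix7
        bad = model.copy()
        _complete_sugar(bad.residues[3], "C2'-endo")
        fixed = rotamerize(bad, 3, 3, grid=grid)
        for i in (0, 1, 5, 6):  # outside span {2, 3}
            for nm in bad.residues[i]:
                assert np.array_equal(fixed.residues[i][nm], bad.residues[i][nm])

    def test_junction_torsions_preserved(self, helix7):
        _, model, grid, _ = helix7
        out = rotamerize(model.copy(), 2, 4, grid=grid)
        pre = model.suite_torsions(2)
        post = out.suite_torsions(2)
        for t_idx in (3, 4, 5):  # alpha, beta, gamma at the 5' junction
            dev = abs((post[t_idx] - pre[t_idx] + 180) % 360 - 180)
            assert dev < 10.0
        pre5 = model.suite_torsions(5)
        post5 = out.suite_torsions(5)
        for t_idx in (1, 2):  # epsilon, zeta at the 3' junction
            dev = abs((post5[t_idx] - pre5[t_idx] + 180) % 360 - 180)
            assert dev < 10.0

    def test_bad_span_rejected(self, helix7):
        _, model, _, _ = helix7
        with pytest.raises(IndexError):
            rotamerize(model.copy(), 3, 99)


class TestAlternateConformers:
    def test_same_conformer_swap_is_nearly_identity(self, helix7):
        _, model, grid, _ = helix7
        work = model.copy()
        work.conformers = list(model.conformers)
        out = rebuild_with_conformer(work, 3, "1a", grid=grid)
        rms = np.sqrt(
            np.mean(
                [
                    np.sum((out.residues[i][nm] - model.residues[i][nm]) ** 2)
                    for i in range(len(model))
                    for nm in model.residues[i]
                ]
            )
        )
        assert rms < 0.2

    def test_same_pucker_swap_leaves_neighbours_untouched(self, helix7):
        _, model, grid, _ = helix7
        work = model.copy()
        work.conformers = list(model.conformers)
        out = rebuild_with_conformer(work, 3, "1c", grid=grid)  # C3'->C3' like 1a
        for i in (0, 1, 5, 6):
            for nm in work.residues[i]:
                assert np.array_equal(out.residues[i][nm], work.residues[i][nm])
        assert out.conformers[2] == "1c"

    def test_pucker_changing_swap_rebuilds_adjacent_suite(self, helix7):
        _, model, grid, _ = helix7
        work = model.copy()
        work.conformers = list(model.conformers)
        out = rebuild_with_conformer(work, 3, "2a", grid=grid)  # needs C2'-endo lead
        lib = load_library()
        assert out.conformers[2] == "2a"
        # the upstream suite must now end C2'-endo, matching 2a's lead
        up = out.conformers[1]
        assert lib[up].ending_pucker == "C2'-endo"
        # shared sugar's actual pucker agrees
        assert out.pucker(2) == "C2'-endo"

    def test_unknown_conformer_rejected(self, helix7):
        from rnatrace.conformers import apply_alternate

        _, model, grid, _ = helix7
        with pytest.raises(KeyError):
            apply_alternate(model.copy(), 3, "zz", grid=grid)


class TestSuiteResidual:
    def test_forward_built_model_has_tiny_residuals(self, mixed7):
        spec, model, _, _ = mixed7
        for j, name in enumerate(spec.conformer_names(), start=1):
            assert suite_residual(model, j, name) < 1e-6
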