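"""Superposition, RMSD/RMSF and distance metrics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nmrens.geometry import (
    ca_distance,
    cross_rmsd,
    distance_series,
    ensemble_rmsd,
    hbond_distance,
    kabsch_superpose,
    rmsd_between,
    rmsf,
)
from nmrens.io_formats import Atom, Ensemble, Selection, StructureModel
from nmrens.synthetic import EnsembleSpec, make_dimer_ensemble

from conftest import ca_ensemble, horn_quaternion_superpose, model_from_coords


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        res = kabsch_superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.rotation == pytest.approx(np.eye(3), abs=1e-10)

    def test_pure_translation_recovered(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(6, 3))
        res = kabsch_superpose(P, P + np.array([5.0, 0.0, 0.0]))
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert res.translation == pytest.approx([5.0, 0.0, 0.0], abs=1e-10)

    def test_rotation_plus_noise_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(4, 3))
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ R90.T + rng.normal(0, 0.1, size=(4, 3))
        res = kabsch_superpose(P, Q)
        _, oracle_rmsd = horn_quaternion_superpose(P, Q)
        assert 0.0 <= res.rmsd <= 0.35
        assert res.rmsd == pytest.approx(oracle_rmsd, abs=1e-6)

    def test_rotation_is_always_proper(self):
        # a near-reflection case: mirror-image point set
        rng = np.random.default_rng(3)
        P = rng.normal(size=(8, 3))
        Q = P * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_scipy_align_vectors_cross_check(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3))
        res = kabsch_superpose(P, Q)
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(12), abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def _shifted_pair(d=2.0):
    rng = np.random.default_rng(5)
    base = {("A", r, "CA"): rng.normal(size=3) * 5 for r in range(1, 9)}
    m1 = model_from_coords(base, 1)
    m2 = model_from_coords({k: np.asarray(v) + [d, 0, 0] for k, v in base.items()}, 2)
    return m1, m2


class TestRmsdBetween:
    def test_self_rmsd_zero(self):
        m1, _ = _shifted_pair()
        assert rmsd_between(m1, m1, Selection.calpha()) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_displacement_without_superposition(self):
        m1, m2 = _shifted_pair(d=2.0)
        r = rmsd_between(m1, m2, Selection.calpha(), superpose=False)
        assert r == pytest.approx(2.0, abs=1e-12)
        # superposition removes a rigid shift entirely
        assert rmsd_between(m1, m2, Selection.calpha()) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_after_superposition(self):
        rng = np.random.default_rng(6)
        c1 = {("A", r, "CA"): rng.normal(size=3) * 4 for r in range(1, 11)}
        c2 = {k: rng.normal(size=3) * 4 for k in c1}
        m1, m2 = model_from_coords(c1, 1), model_from_coords(c2, 2)
        ab = rmsd_between(m1, m2, Selection.calpha())
        ba = rmsd_between(m2, m1, Selection.calpha())
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_invariant_to_rigid_transform_of_either_model(self):
        rng = np.random.default_rng(7)
        c1 = {("A", r, "CA"): rng.normal(size=3) * 4 for r in range(1, 11)}
        c2 = {k: rng.normal(size=3) * 4 for k in c1}
        m1, m2 = model_from_coords(c1, 1), model_from_coords(c2, 2)
        base = rmsd_between(m1, m2, Selection.calpha())
        R = Rotation.from_euler("xyz", [31, -57, 113], degrees=True).as_matrix()
        moved = model_from_coords(
            {k: R @ np.asarray(v) + [3, -8, 12] for k, v in c2.items()}, 2
        )
        assert rmsd_between(m1, moved, Selection.calpha()) == pytest.approx(
            base, abs=1e-9
        )

    def test_chain_mapping_picks_lower_rmsd(self):
        rng = np.random.default_rng(8)
        protomer = {r: rng.normal(size=3) * 5 for r in range(1, 7)}
        other = {r: rng.normal(size=3) * 5 for r in range(1, 7)}
        # model 1: chains A (protomer) and B (other)
        c1 = {("A", r, "CA"): v for r, v in protomer.items()}
        c1.update({("B", r, "CA"): np.asarray(v) + [20, 0, 0] for r, v in other.items()})
        # model 2: same content with swapped chain labels
        c2 = {("B", r, "CA"): v for r, v in protomer.items()}
        c2.update({("A", r, "CA"): np.asarray(v) + [20, 0, 0] for r, v in other.items()})
        m1, m2 = model_from_coords(c1, 1), model_from_coords(c2, 2)
        r_min, cmap = cross_rmsd(m1, m2, Selection.calpha())
        assert r_min == pytest.approx(0.0, abs=1e-9)
        assert cmap == {"A": "B", "B": "A"}


class TestEnsembleRmsd:
    def test_identical_models_all_zero(self):
        frames = np.tile(np.random.default_rng(9).normal(size=(1, 8, 3)), (4, 1, 1))
        ens = ca_ensemble(frames)
        res = ensemble_rmsd(ens, Selection.calpha())
        assert res.per_model == pytest.approx([0.0] * 4, abs=1e-9)

    def test_reference_out_of_range(self):
        frames = np.random.default_rng(10).normal(size=(3, 8, 3))
        with pytest.raises(IndexError):
            ensemble_rmsd(ca_ensemble(frames), Selection.calpha(), reference=5)

    def test_mean_matches_analytic_expectation_for_gaussian_noise(self):
        # iid sigma noise on every coordinate of mobile and reference:
        # E[RMSD^2] ~ 6 sigma^2, superposition removes little for many atoms
        sigma = 0.5
        rng = np.random.default_rng(11)
        base = rng.normal(size=(1, 200, 3)) * 10
        frames = base + rng.normal(0, sigma, size=(12, 200, 3))
        res = ensemble_rmsd(ca_ensemble(frames), Selection.calpha())
        expected = sigma * np.sqrt(6.0)
        assert res.mean == pytest.approx(expected, rel=0.15)


class TestRmsf:
    def test_identical_models_zero(self):
        frames = np.tile(np.random.default_rng(12).normal(size=(1, 6, 3)), (3, 1, 1))
        prof = rmsf(ca_ensemble(frames))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in prof.values.values())

    def test_two_model_displacement_gives_half_amplitude(self):
        rng = np.random.default_rng(13)
        base = rng.normal(size=(20, 3)) * 8
        moved = base.copy()
        moved[10] += [2.0, 0.0, 0.0]  # one residue displaced by 2 A
        ens = ca_ensemble(np.stack([base, moved]))
        # fit on the untouched residues so the displacement is not absorbed
        fit = Selection.calpha(residue_ranges=[(1, 10), (12, 20)])
        prof = rmsf(ens, fit_sel=fit)
        assert prof.values[("A", 11)] == pytest.approx(1.0, abs=0.02)
        assert prof.values[("A", 3)] == pytest.approx(0.0, abs=0.02)

    def test_loop_vs_core_sigma_ordering_recovered(self):
        spec = EnsembleSpec(n_models=10, sigma_core=0.2, sigma_loop=1.5, seed=3)
        ens, truth = make_dimer_ensemble(spec)
        prof = rmsf(ens)
        core_max = max(
            prof.values[("A", r)] for r in truth.core_residues
        )
        assert all(
            prof.values[("A", r)] > core_max for r in truth.loop_residues
        )


class TestDistances:
    def test_ca_distance_pythagoras(self):
        m = model_from_coords(
            {("A", 1, "CA"): (0, 0, 0), ("B", 1, "CA"): (3, 4, 0)}
        )
        assert ca_distance(m, "A", 1, "B", 1) == pytest.approx(5.0)
        assert ca_distance(m, "A", 1, "A", 1) == 0.0

    def test_ca_distance_missing_atom(self):
        m = model_from_coords({("A", 1, "CA"): (0, 0, 0)})
        with pytest.raises(KeyError):
            ca_distance(m, "A", 1, "B", 1)

    def test_distance_series_constant_and_linear(self):
        base = {("A", 1, "CA"): (0.0, 0.0, 0.0), ("B", 1, "CA"): (4.0, 0.0, 0.0)}
        const = Ensemble([model_from_coords(base, i + 1) for i in range(3)])
        res = distance_series(const, ("A", 1, "CA"), ("B", 1, "CA"))
        assert len(res.distances) == 3
        assert res.distances == pytest.approx([4.0] * 3)

        moving = Ensemble(
            [
                model_from_coords(
                    {("A", 1, "CA"): (0.0, 0.0, 0.0),
                     ("B", 1, "CA"): (4.0 + i, 0.0, 0.0)},
                    i + 1,
                )
                for i in range(4)
            ]
        )
        res2 = distance_series(moving, ("A", 1, "CA"), ("B", 1, "CA"))
        assert np.all(np.diff(res2.distances) == pytest.approx(1.0))


class TestHbondDistance:
    def test_ideal_alpha_helix_i4_in_hbond_range(self, ideal_alpha):
        d, conv = hbond_distance(ideal_alpha, "A", 4, 4, use_hydrogen="never")
        assert conv == "O...N"
        assert 2.8 <= d <= 3.2

    def test_extended_chain_far_apart(self, ideal_extended):
        d, _ = hbond_distance(ideal_extended, "A", 4, 4, use_hydrogen="never")
        assert d > 6.5

    def test_hydrogen_used_when_present(self, ideal_alpha):
        d, conv = hbond_distance(ideal_alpha, "A", 4, 4)
        assert conv == "O...H"
        assert d < 2.7

    def test_explicit_distance(self):
        m = model_from_coords(
            {("A", 1, "O"): (0, 0, 0), ("A", 1, "C"): (1, 1, 1),
             ("A", 4, "N"): (4.2, 0, 0), ("A", 4, "CA"): (5, 1, 0)}
        )
        d, conv = hbond_distance(m, "A", 1, 3)
        assert d == pytest.approx(4.2)
        assert conv == "O...N"

    def test_bad_offset_rejected(self, ideal_alpha):
        with pytest.raises(ValueError):
            hbond_distance(ideal_alpha, "A", 4, 5)
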