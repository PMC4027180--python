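"""Kabsch superposition, ensemble precision and backbone torsions."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from wingbind import structqc, synthdata
from wingbind.structqc import StructureEnsemble, ensemble_rmsd, kabsch


def random_points(rng, n=8):
    return rng.normal(0, 5.0, (n, 3))


def oracle_min_rmsd(ref, mov):
    """Independent oracle: Euler-angle grid + Nelder-Mead over rotations,
    centroids aligned analytically."""
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)

    def cost(angles):
        r = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((mov_c @ r.T - ref_c) ** 2, axis=1)))

    best = math.inf
    grid = np.linspace(-np.pi, np.pi, 7)
    for a in grid:
        for b in np.linspace(-np.pi / 2, np.pi / 2, 5):
            for c in grid:
                res = minimize(cost, [a, b, c], method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12,
                                        "maxiter": 2000})
                best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        p = random_points(rng)
        sup = kabsch(p, p)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert sup.rotation == pytest.approx(np.eye(3), abs=1e-12)

    def test_pure_translation(self):
        rng = np.random.default_rng(1)
        p = random_points(rng)
        sup = kabsch(p, p + np.array([3.0, -2.0, 7.0]))
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert sup.translation == pytest.approx([-3.0, 2.0, -7.0], abs=1e-10)

    def test_90_degree_rotation(self):
        rng = np.random.default_rng(2)
        p = random_points(rng)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        sup = kabsch(p, p @ rot.T)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_reflection_not_allowed(self):
        """A mirrored set must NOT be superposed to zero by a proper rotation."""
        rng = np.random.default_rng(3)
        p = random_points(rng)
        mirrored = p * np.array([-1.0, 1.0, 1.0])
        sup = kabsch(p, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)
        assert sup.rmsd > 0.1

    def test_matches_rotation_search_oracle(self):
        """20 random 5-point pairs: Kabsch RMSD equals the Euler-grid +
        Nelder-Mead minimum within 1e-3 A."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            ref = random_points(rng, n=5)
            mov = random_points(rng, n=5)
            assert kabsch(ref, mov).rmsd == pytest.approx(
                oracle_min_rmsd(ref, mov), abs=1e-3)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)
        with pytest.raises(ValueError, match="3 points"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="N x 3"):
            kabsch(np.zeros((4, 3)), np.zeros((5, 3)))


class TestEnsembleRmsd:
    def test_noiseless_ensemble_superposes_exactly(self, spec0):
        ens = synthdata.gen_ensemble(spec0)
        res = ensemble_rmsd(ens)
        assert res.mean_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_ensemble_rmsd_tracks_jitter(self, spec):
        # coordinate jitter sigma 0.3 A per axis: RMSD to the mean is close
        # to sigma * sqrt(3 * (1 - 1/n_models))
        ens = synthdata.gen_ensemble(spec)
        res = ensemble_rmsd(ens)
        sigma = spec.noise["ensemble"]
        expect = sigma * math.sqrt(3 * (1 - 1 / len(ens)))
        assert res.mean_rmsd == pytest.approx(expect, rel=0.15)

    def test_rigid_transform_invariance(self, spec):
        """Rotating+translating one model does not change the precision."""
        ens = synthdata.gen_ensemble(spec)
        base = ensemble_rmsd(ens).mean_rmsd
        rot = Rotation.from_euler("zyx", [0.3, -1.1, 2.0]).as_matrix()
        m = ens.models[0].copy()
        xyz = m[["x", "y", "z"]].to_numpy(float) @ rot.T + [10.0, -4.0, 2.5]
        m[["x", "y", "z"]] = xyz
        moved = StructureEnsemble(models=[m] + [x.copy() for x in ens.models[1:]])
        assert ensemble_rmsd(moved).mean_rmsd == pytest.approx(base, abs=1e-6)

    def test_residue_window_selection(self, spec):
        ens = synthdata.gen_ensemble(spec)
        res = ensemble_rmsd(ens, residue_range=(5, 15))
        n_atoms = res.mean_coords.shape[0]
        assert n_atoms == 11 * 4        # N, CA, C, O per residue

    def test_single_model_rejected(self, spec0):
        ens = synthdata.gen_ensemble(spec0, n_models=1)
        with pytest.raises(ValueError, match="2 models"):
            ensemble_rmsd(ens)

    def test_mismatched_rosters_rejected(self, spec0):
        ens = synthdata.gen_ensemble(spec0, n_models=3)
        models = [m.copy() for m in ens.models]
        models[1] = models[1].iloc[:-1]
        bad = StructureEnsemble(models=models)
        with pytest.raises(ValueError, match="roster"):
            bad.select()


class TestBackboneTorsions:
    def test_builder_round_trips_phi_psi(self):
        model = synthdata.build_backbone([(-57.0, -47.0)] * 8)
        for res in range(2, 8):
            phi, psi = structqc.dihedrals(model, res)
            assert phi == pytest.approx(-57.0, abs=1e-6)
            assert psi == pytest.approx(-47.0, abs=1e-6)

    def test_termini_return_none(self):
        model = synthdata.build_backbone([(-57.0, -47.0)] * 5)
        phi1, _ = structqc.dihedrals(model, 1)
        _, psi_last = structqc.dihedrals(model, 5)
        assert phi1 is None and psi_last is None

    def test_dihedral_rotation_invariance(self):
        model = synthdata.build_backbone([(-70.0, 140.0)] * 6)
        rot = Rotation.from_euler("zyx", [0.7, 0.2, -0.9]).as_matrix()
        moved = model.copy()
        moved[["x", "y", "z"]] = \
            model[["x", "y", "z"]].to_numpy(float) @ rot.T + [1.0, 2.0, 3.0]
        for res in (2, 3, 4):
            a = structqc.dihedrals(model, res)
            b = structqc.dihedrals(moved, res)
            assert a[0] == pytest.approx(b[0], abs=1e-8)
            assert a[1] == pytest.approx(b[1], abs=1e-8)

    def test_rama_labels(self):
        assert structqc.rama_label(-57.0, -47.0) == "favored-like"   # alpha
        assert structqc.rama_label(-120.0, 130.0) == "favored-like"  # beta
        assert structqc.rama_label(60.0, 60.0) == "other"
        assert structqc.rama_label(None, -47.0) == "other"

    def test_helical_geometry_is_favored(self, spec0):
        ens = synthdata.gen_ensemble(spec0, n_models=2)
        model = ens.models[0]
        labels = [structqc.rama_label(*structqc.dihedrals(model, r))
                  for r in range(2, 20)]
        assert all(lab == "favored-like" for lab in labels)
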