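"""Refinement and the iterative multi-lattice indexing driver."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mxindex import IndexingConfig, RefineOptions, random_crystal
from mxindex.assign import UNASSIGNED, assign_multilattice
from mxindex.geometry import Crystal, frame_to_phi, spots_to_rlp
from mxindex.refine import index_multi_lattice, predict_centroids, refine_joint, refine_single
from mxindex.search import IndexingFailure
from mxindex.simulate import SimulationSpec, compose_lattices, simulate_multi_lattice
from mxindex.symmetry import match_orientations, misorientation_deg


def _assignments_for(table, crystals, experiment, tol=0.3):
    r = spots_to_rlp(table, experiment)
    return r, assign_multilattice(r, crystals, tol)


class TestPredictCentroids:
    def test_self_consistency_on_noise_free_spots(self, single_lattice_sim):
        table, truth, experiment = single_lattice_sim
        r, assignments = _assignments_for(table, truth, experiment)
        phi_obs = frame_to_phi(table["z"].to_numpy(), experiment.scan)
        pred = predict_centroids(truth[0], experiment, assignments, phi_obs)
        merged = pred.set_index("spot_id")
        obs = table.reset_index(drop=True)
        sid = merged.index.to_numpy().astype(int)
        assert len(sid) == len(table)
        assert np.abs(obs["x_px"].to_numpy()[sid] - merged["x_px"].to_numpy()).max() < 1e-6
        assert np.abs(obs["y_px"].to_numpy()[sid] - merged["y_px"].to_numpy()).max() < 1e-6
        assert np.abs(obs["z"].to_numpy()[sid] - merged["z"].to_numpy()).max() < 1e-6

    def test_displacement_linear_in_misorientation(self, single_lattice_sim):
        """Centroid shifts scale linearly for small orientation errors."""
        table, truth, experiment = single_lattice_sim
        _, assignments = _assignments_for(table, truth, experiment)
        phi_obs = frame_to_phi(table["z"].to_numpy(), experiment.scan)
        base = predict_centroids(truth[0], experiment, assignments, phi_obs).set_index("spot_id")

        def displaced(angle_deg):
            rot = Rotation.from_rotvec(np.radians(angle_deg) * np.array([0, 0, 1.0])).as_matrix()
            c = Crystal(U=rot @ truth[0].U, cell=truth[0].cell)
            p = predict_centroids(c, experiment, assignments, phi_obs).set_index("spot_id")
            common = base.index.intersection(p.index)
            return (p.loc[common, ["x_px", "y_px"]] - base.loc[common, ["x_px", "y_px"]]), common

        d1, c1 = displaced(0.01)
        d2, c2 = displaced(0.02)
        common = c1.intersection(c2)
        ratio = np.linalg.norm(d2.loc[common].to_numpy()) / np.linalg.norm(d1.loc[common].to_numpy())
        assert ratio == pytest.approx(2.0, rel=0.05)


class TestRefineSingle:
    def test_fixed_point_at_truth(self, single_lattice_sim, cubic_cell):
        table, truth, experiment = single_lattice_sim
        _, assignments = _assignments_for(table, truth, experiment)
        res = refine_single(
            truth[0], assignments, table, experiment, RefineOptions(target_cell=cubic_cell)
        )
        assert res.converged
        assert max(res.rmsd[:2]) < 1e-6
        assert misorientation_deg(res.crystals[0], truth[0]) < 1e-6

    def test_recovers_misoriented_start(self, cubic_cell, wedge_experiment):
        rng = np.random.default_rng(31)
        truth = random_crystal(cubic_cell, rng)
        spec = SimulationSpec(
            crystals=[truth], geometry=wedge_experiment, d_min=4.0,
            noise_sd=(0.3, 0.3, 0.3), seed=31,
        )
        table, _ = simulate_multi_lattice(spec)
        rot = Rotation.from_rotvec(np.radians(0.3) * np.array([0.6, 0.8, 0.0])).as_matrix()
        start = Crystal(U=rot @ truth.U, cell=cubic_cell)
        r = spots_to_rlp(table, wedge_experiment)
        assignments = assign_multilattice(r, [start], 0.3)
        res = refine_single(
            start, assignments, table, wedge_experiment, RefineOptions(target_cell=cubic_cell)
        )
        assert res.converged
        assert misorientation_deg(res.crystals[0], truth) < 0.05

    def test_objective_non_increasing(self, cubic_cell, wedge_experiment):
        rng = np.random.default_rng(32)
        truth = random_crystal(cubic_cell, rng)
        spec = SimulationSpec(
            crystals=[truth], geometry=wedge_experiment, d_min=4.0,
            noise_sd=(0.3, 0.3, 0.3), seed=32,
        )
        table, _ = simulate_multi_lattice(spec)
        rot = Rotation.from_rotvec(np.radians(0.2) * np.array([0, 1.0, 0])).as_matrix()
        start = Crystal(U=rot @ truth.U, cell=cubic_cell)
        r = spots_to_rlp(table, wedge_experiment)
        assignments = assign_multilattice(r, [start], 0.3)
        res = refine_single(
            start, assignments, table, wedge_experiment, RefineOptions(target_cell=cubic_cell)
        )
        # accepted steps only: the final objective beats the starting one
        assert res.history[-1] <= res.history[0]
        assert res.crystals[0].U @ res.crystals[0].U.T == pytest.approx(np.eye(3), abs=1e-8)


class TestRefineJoint:
    def test_single_crystal_reduction(self, single_lattice_sim, cubic_cell):
        table, truth, experiment = single_lattice_sim
        _, assignments = _assignments_for(table, truth, experiment)
        opt = RefineOptions(target_cell=cubic_cell)
        a = refine_single(truth[0], assignments, table, experiment, opt)
        b = refine_joint(list(truth), assignments, table, experiment, opt)
        assert np.allclose(a.crystals[0].A, b.crystals[0].A, atol=1e-12)

    def test_separability_under_fixed_geometry(self, cubic_cell, wedge_experiment):
        rng = np.random.default_rng(33)
        truth = [random_crystal(cubic_cell, rng) for _ in range(2)]
        spec = SimulationSpec(
            crystals=truth, geometry=wedge_experiment, d_min=4.0, noise_sd=(0, 0, 0), seed=33
        )
        table, _ = simulate_multi_lattice(spec)
        r, assignments = _assignments_for(table, truth, wedge_experiment)
        opt = RefineOptions(target_cell=cubic_cell)
        joint = refine_joint(list(truth), assignments, table, wedge_experiment, opt)
        # drop lattice 1's spots: lattice 0's parameters must not move
        only0 = table[table["true_lattice"] == 0].reset_index(drop=True)
        r0, assign0 = _assignments_for(only0, [truth[0]], wedge_experiment)
        solo = refine_single(truth[0], assign0, only0, wedge_experiment, opt)
        assert np.abs(joint.crystals[0].A - solo.crystals[0].A).max() < 1e-8


class TestIndexMultiLattice:
    def test_single_lattice_noise_free(self, single_lattice_sim, cubic_cell):
        table, truth, experiment = single_lattice_sim
        result = index_multi_lattice(table, experiment, cubic_cell)
        assert result.n_lattices == 1
        clean = result.assignments
        frac = ((clean.lattice_id != UNASSIGNED) & ~clean.outlier).mean()
        assert frac == 1.0
        assert misorientation_deg(result.crystals[0], truth[0]) < 0.01

    def test_six_lattices_recovered(self, six_lattice_sim, cubic_cell):
        table, truth, experiment = six_lattice_sim
        result = index_multi_lattice(table, experiment, cubic_cell)
        assert result.n_lattices == 6
        match, angles = match_orientations(result.crystals, truth)
        assert sorted(match.tolist()) == list(range(6))
        assert np.nanmax(angles) <= 0.05

    def test_spurious_only_input_fails_cleanly(self, cubic_cell, wedge_experiment):
        empty = []
        table = compose_lattices(empty, n_spurious=400, seed=55, geometry=wedge_experiment)
        with pytest.raises(IndexingFailure):
            index_multi_lattice(table, wedge_experiment, cubic_cell)

    def test_spurious_spots_filtered(self, cubic_cell, wedge_experiment):
        """Most spurious spots end up unassigned or flagged; real ones survive."""
        rng = np.random.default_rng(56)
        truth = [random_crystal(cubic_cell, rng) for _ in range(2)]
        spec = SimulationSpec(
            crystals=truth, geometry=wedge_experiment, d_min=4.0,
            noise_sd=(0.3, 0.3, 0.3), n_spurious=80, seed=56,
        )
        table, _ = simulate_multi_lattice(spec)
        result = index_multi_lattice(table, wedge_experiment, cubic_cell)
        spurious = (table["true_lattice"] == -1).to_numpy()
        clean = (
            (result.assignments["lattice_id"] != UNASSIGNED)
            & ~result.assignments["outlier"]
        ).to_numpy()
        # spurious spots that survive as clean assignments
        assert clean[spurious].mean() <= 0.10
        # genuine spots flagged as outliers
        flagged_true = result.assignments["outlier"].to_numpy()[~spurious]
        assert flagged_true.mean() <= 0.01

    def test_row_order_invariance(self, cubic_cell, wedge_experiment):
        rng = np.random.default_rng(57)
        truth = [random_crystal(cubic_cell, rng) for _ in range(2)]
        spec = SimulationSpec(
            crystals=truth, geometry=wedge_experiment, d_min=4.0,
            noise_sd=(0.3, 0.3, 0.3), seed=57,
        )
        table, _ = simulate_multi_lattice(spec)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        res1 = index_multi_lattice(table, wedge_experiment, cubic_cell)
        res2 = index_multi_lattice(shuffled, wedge_experiment, cubic_cell)
        assert res1.n_lattices == res2.n_lattices
        m, angles = match_orientations(res1.crystals, res2.crystals)
        assert np.nanmax(angles) < 1e-3
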