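"""Superposition, center-of-mass series, correlation matrices, network assembly."""

import itertools

import numpy as np
import pytest

from clampscan.mdnet import (
    CorrelationMatrix,
    NetworkParams,
    TrajectoryEnsemble,
    align_frames,
    assemble_network,
    average_correlations,
    com_series,
    contact_frequency,
    generalized_correlation,
    kabsch_superpose,
    linear_correlation,
    read_xyz_table,
    stitch_correlations,
    write_xyz_table,
)
from clampscan.synthetic import simulate_trajectory


def rotation_matrix(rng):
    # random proper rotation via QR
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestKabsch:
    def test_identical_sets_superpose_exactly(self, rng):
        pts = rng.standard_normal((8, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.standard_normal((10, 3))
        rot = rotation_matrix(rng)
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        res = kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transformed, pts, atol=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 0.1)

    def test_matches_dense_rotation_grid_oracle(self, rng):
        ref = rng.standard_normal((4, 3))
        mobile = ref + 0.1 * rng.standard_normal((4, 3))
        res = kabsch_superpose(mobile, ref)

        def rmsd_at(rot):
            a = mobile - mobile.mean(axis=0)
            b = ref - ref.mean(axis=0)
            return np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1)))

        def euler(ax, ay, az):
            cx, sx = np.cos(ax), np.sin(ax)
            cy, sy = np.cos(ay), np.sin(ay)
            cz, sz = np.cos(az), np.sin(az)
            rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
            ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
            rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
            return rz @ ry @ rx

        # hierarchical grid search over Euler angles
        center = np.zeros(3)
        width = np.pi
        best = np.inf
        for _ in range(4):
            grid = [np.linspace(c - width, c + width, 11) for c in center]
            for ax, ay, az in itertools.product(*grid):
                r = rmsd_at(euler(ax, ay, az))
                if r < best:
                    best = r
                    center = np.array([ax, ay, az])
            width /= 5.0
        assert res.rmsd == pytest.approx(best, abs=1e-3)


class TestComSeries:
    def _traj(self, atom_coords, masses, atom_residue, n_res):
        f, a, _ = atom_coords.shape
        return TrajectoryEnsemble(
            np.zeros((f, n_res, 3)),
            tuple(("A", i + 1) for i in range(n_res)),
            atom_coords=atom_coords,
            atom_masses=np.asarray(masses, float),
            atom_residue=np.asarray(atom_residue),
        )

    def test_single_atom_residue_is_identity(self, rng):
        coords = rng.standard_normal((5, 1, 3))
        traj = self._traj(coords, [12.0], [0], 1)
        assert np.allclose(com_series(traj), coords)

    def test_equal_masses_average_to_midpoint(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 0] = [1.0, 0, 0]
        coords[0, 1] = [-1.0, 0, 0]
        traj = self._traj(coords, [12.0, 12.0], [0, 0], 1)
        assert np.allclose(com_series(traj)[0, 0], [0.0, 0, 0])

    def test_matches_mass_weighted_sum_oracle(self, rng):
        coords = rng.standard_normal((3, 5, 3))
        masses = rng.uniform(1, 16, size=5)
        traj = self._traj(coords, masses, [0] * 5, 1)
        expected = (coords * masses[None, :, None]).sum(axis=1) / masses.sum()
        assert np.allclose(com_series(traj)[:, 0], expected, atol=1e-12)


class TestLinearCorrelation:
    def test_diagonal_is_one(self):
        traj = simulate_trajectory(3, 500, [], seed=1)
        c = linear_correlation(traj)
        assert np.allclose(np.diag(c.values), 1.0)
        assert np.allclose(c.values, c.values.T)
        assert np.all(np.abs(c.values) <= 1.0)

    def test_mirror_image_motion_is_minus_one(self, rng):
        d = rng.standard_normal((400, 1, 3))
        coords = np.concatenate([d, -d], axis=1)
        c = linear_correlation(coords)
        assert c.values[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_requested_gaussian_correlation(self):
        traj = simulate_trajectory(2, 4000, [([0, 1], 0.8)], seed=4)
        assert linear_correlation(traj).values[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_zero_variance_residue_rejected(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 0] = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            linear_correlation(coords)


class TestGeneralizedCorrelation:
    def test_independent_residues_near_zero(self):
        traj = simulate_trajectory(2, 4000, [], seed=5)
        assert generalized_correlation(traj).values[0, 1] < 0.1

    def test_isotropic_gaussian_equals_rho(self):
        traj = simulate_trajectory(2, 4000, [([0, 1], 0.8)], seed=6)
        assert generalized_correlation(traj).values[0, 1] == pytest.approx(0.8, abs=0.05)

    def test_deterministic_coupling_saturates(self, rng):
        # the k-NN estimator is finite-sample bounded, so "= 1" shows up as
        # a value far above any attainable Gaussian correlation
        d = rng.standard_normal((2000, 1, 3))
        coords = np.concatenate([d, 2.0 * d + 1.0], axis=1)
        assert generalized_correlation(coords).values[0, 1] > 0.95

    def test_agrees_with_linear_on_isotropic_gaussians(self):
        # same-information check across the correlation grid, using the
        # default analysis mode: matrices averaged over four trajectories
        for i, rho in enumerate((0.0, 0.3, 0.6, 0.9)):
            blocks = [([0, 1], rho)] if rho else []
            lins, gens = [], []
            for t in range(4):
                traj = simulate_trajectory(2, 4000, blocks, seed=40 + 10 * i + t)
                lins.append(linear_correlation(traj))
                gens.append(generalized_correlation(traj))
            lin = abs(average_correlations(lins).values[0, 1])
            gen = average_correlations(gens).values[0, 1]
            assert abs(gen - lin) < 0.05, f"rho={rho}"

    def test_k_must_be_less_than_frames(self):
        traj = simulate_trajectory(2, 10, [], seed=1)
        with pytest.raises(ValueError):
            generalized_correlation(traj, k_neighbors=10)


class TestRigidInvariance:
    def test_correlations_unchanged_by_global_motion_after_alignment(self, rng):
        traj = simulate_trajectory(4, 600, [([0, 1], 0.6)], seed=9)
        ref = traj.coords[0]
        base = align_frames(traj.coords, range(4), reference=ref)
        base_lin = linear_correlation(base).values
        base_gen = generalized_correlation(base).values
        moved = np.empty_like(traj.coords)
        for f in range(traj.n_frames):
            rot = rotation_matrix(rng)
            moved[f] = traj.coords[f] @ rot.T + rng.uniform(-50, 50, size=3)
        aligned = align_frames(moved, range(4), reference=ref)
        assert np.allclose(linear_correlation(aligned).values, base_lin, atol=1e-6)
        assert np.allclose(generalized_correlation(aligned).values, base_gen, atol=1e-6)


class TestContactFrequency:
    def _toggling_pair(self, n_contact, n_total):
        coords = np.zeros((n_total, 2, 3))
        coords[:, 1, 0] = 20.0
        coords[:n_contact, 1, 0] = 5.0
        labels = (("A", 1), ("A", 2))
        return TrajectoryEnsemble(coords, labels)

    def test_always_in_contact(self):
        freq = contact_frequency(self._toggling_pair(20, 20), cutoff=6.5)
        assert freq[0, 1] == 1.0

    def test_never_in_contact(self):
        freq = contact_frequency(self._toggling_pair(0, 20), cutoff=6.5)
        assert freq[0, 1] == 0.0

    def test_seven_of_twenty_frames(self):
        freq = contact_frequency(self._toggling_pair(7, 20), cutoff=6.5)
        assert freq[0, 1] == pytest.approx(0.35)


class TestAssembleNetwork:
    def _corr(self, values, labels):
        return CorrelationMatrix(np.array(values), "linear", labels)

    def test_thresholds_and_adjacency(self):
        labels = (("A", 1), ("A", 2), ("A", 5))
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.9  # adjacent: must be dropped
        c[0, 2] = c[2, 0] = 0.4  # passes
        c[1, 2] = c[2, 1] = 0.30  # below 0.35: dropped
        freq = np.full((3, 3), 0.5)
        edges = assemble_network(self._corr(c, labels), freq)
        got = {(r["residue_i"], r["residue_j"]) for _, r in edges.iterrows()}
        assert got == {(1, 5)}

    def test_contact_gate(self):
        labels = (("A", 1), ("A", 5))
        c = np.array([[1.0, 0.8], [0.8, 1.0]])
        low = np.array([[1.0, 0.2], [0.2, 1.0]])
        high = np.array([[1.0, 0.35], [0.35, 1.0]])
        assert assemble_network(self._corr(c, labels), low).empty
        assert len(assemble_network(self._corr(c, labels), high)) == 1

    def test_generalized_threshold_is_higher(self):
        labels = (("A", 1), ("A", 5))
        vals = np.array([[1.0, 0.45], [0.45, 1.0]])
        freq = np.full((2, 2), 1.0)
        lin = assemble_network(CorrelationMatrix(vals, "linear", labels), freq)
        gen = assemble_network(CorrelationMatrix(vals, "generalized", labels), freq)
        assert len(lin) == 1 and gen.empty

    def test_edges_subset_of_contact_graph(self, rng):
        traj = simulate_trajectory(6, 200, [([0, 3], 0.9), ([1, 4], 0.9)], seed=11)
        freq = contact_frequency(traj, cutoff=15.0)
        corr = linear_correlation(traj)
        edges = assemble_network(corr, freq, NetworkParams(contact_freq_min=0.35))
        for _, e in edges.iterrows():
            i = corr.labels.index((e["chain_i"], e["residue_i"]))
            j = corr.labels.index((e["chain_j"], e["residue_j"]))
            assert freq[i, j] >= 0.35


class TestMergingMatrices:
    def test_average_of_identical_matrices_is_identity(self):
        traj = simulate_trajectory(3, 300, [], seed=13)
        c = linear_correlation(traj)
        avg = average_correlations([c, CorrelationMatrix(c.values.copy(), c.kind, c.labels)])
        assert np.allclose(avg.values, c.values)

    def test_stitch_blocks_with_cross_terms(self):
        la = (("B", 1), ("B", 2))
        lb = (("C", 1), ("C", 2))
        wa = CorrelationMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), "linear", la)
        wb = CorrelationMatrix(np.array([[1.0, -0.2], [-0.2, 1.0]]), "linear", lb)
        cross_vals = np.full((4, 4), 0.1)
        np.fill_diagonal(cross_vals, 1.0)
        cross = CorrelationMatrix(cross_vals, "linear", la + lb)
        merged = stitch_correlations([wa, wb], [cross])
        assert merged.values[0, 1] == 0.5  # within-block value wins
        assert merged.values[2, 3] == -0.2
        assert merged.values[0, 2] == 0.1  # cross-block from the pair matrix
        assert np.allclose(np.diag(merged.values), 1.0)


class TestXyzTable:
    def test_residue_table_round_trip(self, tmp_path):
        traj = simulate_trajectory(3, 5, [], seed=17)
        path = tmp_path / "traj.tsv"
        write_xyz_table(traj, path)
        back = read_xyz_table(path)
        assert back.labels == traj.labels
        assert np.allclose(back.coords, traj.coords)

    def test_atom_table_computes_centers_of_mass(self, tmp_path):
        import pandas as pd

        rows = []
        for frame in range(2):
            rows.append((frame, "A", 1, 1.0 + frame, 0.0, 0.0, "N", 14.0))
            rows.append((frame, "A", 1, 3.0 + frame, 0.0, 0.0, "C", 14.0))
        df = pd.DataFrame(rows, columns=["frame", "chain", "residue", "x", "y", "z", "atom", "mass"])
        path = tmp_path / "atoms.tsv"
        df.to_csv(path, sep="\t", index=False)
        traj = read_xyz_table(path)
        assert np.allclose(traj.coords[:, 0, 0], [2.0, 3.0])
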