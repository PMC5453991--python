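"""Volume/model I/O, interpolation, superposition and filtering."""

import gemmi
import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from emtracer import volio
from emtracer.fixtures import SimulationSpec, make_ideal_helix, simulate_map, toy_protein
from emtracer.volio import (
    GridMap,
    interpolate,
    lowpass_filter,
    read_map,
    read_model,
    superpose,
    write_map,
    write_model,
)


@pytest.fixture
def small_map():
    rng = np.random.default_rng(7)
    data = rng.normal(size=(12, 10, 8))
    return GridMap(data, voxel_size=1.06, origin=np.array([3.0, -2.0, 1.5]))


class TestMapIO:
    def test_round_trip_identity(self, small_map, tmp_path):
        p = tmp_path / "m.mrc"
        write_map(small_map, p)
        again = read_map(p)
        np.testing.assert_allclose(again.data, small_map.data, rtol=0, atol=1e-6)
        np.testing.assert_allclose(again.voxel_size, small_map.voxel_size, rtol=1e-6)
        np.testing.assert_allclose(again.origin, small_map.origin, atol=1e-5)
        # second round trip is bit-stable at float32
        p2 = tmp_path / "m2.mrc"
        write_map(again, p2)
        third = read_map(p2)
        np.testing.assert_array_equal(third.data, again.data)

    def test_header_voxel_and_shape(self, tmp_path):
        gmap = GridMap(np.zeros((64, 64, 64)), voxel_size=1.06)
        p = tmp_path / "v.mrc"
        write_map(gmap, p)
        again = read_map(p)
        assert again.shape == (64, 64, 64)
        np.testing.assert_allclose(again.voxel_size, 1.06, rtol=1e-6)

    def test_axis_permutation_canonicalised(self, small_map, tmp_path):
        """A file stored with swapped fast/slow axes reads back identically."""
        p_xyz = tmp_path / "xyz.mrc"
        write_map(small_map, p_xyz)
        # write the same volume with the z axis fastest (mapc=3, maps=1):
        # the stored array is transposed, the header declares the swap
        grid = gemmi.FloatGrid(
            np.ascontiguousarray(
                np.transpose(small_map.data, (2, 1, 0)), dtype=np.float32
            )
        )
        nx, ny, nz = small_map.shape
        grid.unit_cell = gemmi.UnitCell(
            nx * small_map.voxel_size[0],
            ny * small_map.voxel_size[1],
            nz * small_map.voxel_size[2],
            90, 90, 90,
        )
        grid.spacegroup = gemmi.SpaceGroup("P1")
        ccp4 = gemmi.Ccp4Map()
        ccp4.grid = grid
        ccp4.update_ccp4_header()
        for w, v in zip((50, 51, 52), small_map.origin):
            ccp4.set_header_float(w, float(v))
        ccp4.set_header_i32(17, 3)  # mapc = z
        ccp4.set_header_i32(19, 1)  # maps = x
        p_zyx = tmp_path / "zyx.mrc"
        ccp4.write_ccp4_map(str(p_zyx))
        a = read_map(p_xyz)
        b = read_map(p_zyx)
        assert b.shape == a.shape
        np.testing.assert_allclose(a.data, b.data, atol=1e-6)
        np.testing.assert_allclose(a.voxel_size, b.voxel_size, rtol=1e-6)

    def test_rescaled_header(self, small_map, tmp_path):
        scaled = small_map.copy()
        scaled.voxel_size = small_map.voxel_size * 1.03
        p = tmp_path / "s.mrc"
        write_map(scaled, p)
        again = read_map(p)
        np.testing.assert_allclose(
            again.voxel_size, small_map.voxel_size * 1.03, rtol=1e-6
        )

    def test_start_index_origin(self, small_map, tmp_path):
        """With no ORIGIN fields, NXSTART-style headers set the origin."""
        p = tmp_path / "n.mrc"
        write_map(small_map, p)
        ccp4 = gemmi.read_ccp4_map(str(p))
        for w in (50, 51, 52):
            ccp4.set_header_float(w, 0.0)
        ccp4.set_header_i32(5, 4)
        ccp4.write_ccp4_map(str(p))
        again = read_map(p)
        np.testing.assert_allclose(again.origin[0], 4 * small_map.voxel_size[0], atol=1e-5)

    def test_malformed_file_raises(self, tmp_path):
        p = tmp_path / "bad.mrc"
        p.write_bytes(b"not a map at all")
        with pytest.raises(volio.MapFormatError):
            read_map(p)

    def test_invalid_gridmap(self):
        with pytest.raises(ValueError):
            GridMap(np.zeros((1, 5, 5)), voxel_size=1.0)
        with pytest.raises(ValueError):
            GridMap(np.zeros((5, 5, 5)), voxel_size=-1.0)


class TestInterpolate:
    @pytest.fixture(scope="class")
    def blob_map(self):
        ax = np.arange(24)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        data = np.exp(-((X - 12.0) ** 2 + (Y - 11.0) ** 2 + (Z - 13.0) ** 2) / 18.0)
        return GridMap(data, voxel_size=1.0, origin=np.array([-5.0, 2.0, 0.0]))

    @pytest.mark.parametrize("order", ["linear", "cubic"])
    def test_exact_on_grid_nodes(self, blob_map, order):
        idx = np.array([[0, 0, 0], [3, 4, 5], [23, 23, 23], [12, 11, 13]])
        pts = blob_map.index_to_xyz(idx)
        vals = interpolate(blob_map, pts, order=order)
        np.testing.assert_allclose(
            vals, blob_map.data[idx[:, 0], idx[:, 1], idx[:, 2]], atol=1e-10
        )

    @pytest.mark.parametrize("order", ["linear", "cubic"])
    def test_constant_map(self, order):
        gmap = GridMap(np.full((8, 8, 8), 3.25), voxel_size=0.9)
        pts = np.array([[2.3, 3.1, 4.7], [1.0, 1.0, 1.0]])
        np.testing.assert_allclose(interpolate(gmap, pts, order=order), 3.25, atol=1e-9)

    def test_cubic_against_spline_oracle(self, blob_map):
        """Independent separable-spline oracle on a smooth Gaussian blob."""
        rng = np.random.default_rng(11)
        idx = rng.uniform(3, 20, size=(50, 3))
        pts = blob_map.index_to_xyz(idx)
        got = interpolate(blob_map, pts, order="cubic")
        ax = np.arange(24)
        oracle = RegularGridInterpolator(
            (ax, ax, ax), blob_map.data, method="cubic"
        )(idx)
        np.testing.assert_allclose(got, oracle, atol=1e-3)

    def test_outside_returns_sentinel(self, blob_map):
        pts = np.array([[1e4, 0, 0], [-1e4, 0, 0]])
        assert np.all(np.isnan(interpolate(blob_map, pts)))

    def test_empty_points(self, blob_map):
        assert interpolate(blob_map, np.empty((0, 3))).size == 0


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        R, t, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.transform import Rotation

        R_true = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        t_true = np.array([1.0, -2.0, 0.5])
        R, t, rmsd = superpose(pts, pts @ R_true.T + t_true)
        np.testing.assert_allclose(R, R_true, atol=1e-9)
        np.testing.assert_allclose(t, t_true, atol=1e-9)
        assert rmsd < 1e-9

    def test_rmsd_matches_quaternion_oracle(self):
        """Horn's quaternion method as an independent check of the SVD fit."""

        def horn_rmsd(X, Y):
            xc, yc = X.mean(0), Y.mean(0)
            X0, Y0 = X - xc, Y - yc
            Sxx = X0.T @ Y0
            A = Sxx - Sxx.T
            delta = np.array([A[1, 2], A[2, 0], A[0, 1]])
            tr = np.trace(Sxx)
            Q = np.empty((4, 4))
            Q[0, 0] = tr
            Q[0, 1:] = delta
            Q[1:, 0] = delta
            Q[1:, 1:] = Sxx + Sxx.T - tr * np.eye(3)
            lam = np.linalg.eigvalsh(Q)[-1]
            sq = ((X0**2).sum() + (Y0**2).sum() - 2.0 * lam) / len(X)
            return np.sqrt(max(sq, 0.0))

        rng = np.random.default_rng(2)
        for _ in range(5):
            X = rng.normal(size=(6, 3))
            Y = rng.normal(size=(6, 3))
            _, _, rmsd = superpose(X, Y)
            assert abs(rmsd - horn_rmsd(X, Y)) < 1e-6

    def test_forward_backward_inverse(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 3))
        Y = rng.normal(size=(7, 3))
        R1, t1, r1 = superpose(X, Y)
        R2, t2, r2 = superpose(Y, X)
        np.testing.assert_allclose(R1 @ R2, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(R2 @ t1 + t2, 0.0, atol=1e-9)
        assert abs(r1 - r2) < 1e-9

    def test_errors(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            superpose(line, line)


class TestLowpass:
    @pytest.fixture(scope="class")
    def sharp_map(self):
        rng = np.random.default_rng(5)
        return GridMap(rng.normal(size=(32, 32, 32)), voxel_size=1.0)

    def test_power_beyond_cutoff_suppressed(self, sharp_map):
        filtered = lowpass_filter(sharp_map, 4.0)
        F = np.fft.rfftn(filtered.data)
        s = volio._freq_magnitude(filtered.shape, filtered.voxel_size, rfft=True)
        width = 2.0 / 32.0
        beyond = np.abs(F[s > 1.0 / 4.0 + width]) ** 2
        assert beyond.sum() < 1e-6 * (np.abs(F) ** 2).sum()

    def test_mean_preserved(self, sharp_map):
        filtered = lowpass_filter(sharp_map, 4.0)
        assert abs(filtered.data.mean() - sharp_map.data.mean()) < 1e-10

    def test_no_op_when_band_limited(self, sharp_map):
        smooth = lowpass_filter(sharp_map, 8.0)
        again = lowpass_filter(smooth, 4.0)
        np.testing.assert_allclose(again.data, smooth.data, atol=1e-10)

    def test_nyquist_rejected(self, sharp_map):
        with pytest.raises(ValueError):
            lowpass_filter(sharp_map, 2.0)


class TestModelIO:
    def test_helix_round_trip(self, tmp_path):
        model = make_ideal_helix(6)
        p = tmp_path / "h.pdb"
        write_model(model, p)
        again = read_model(p)
        assert again.n_residues() == 6
        assert all(r.ca is not None for r in again.residues())
        np.testing.assert_allclose(
            again.coords(), model.coords(), atol=1.5e-3
        )  # PDB keeps 3 decimals

    def test_helix_records_label_residues(self, tmp_path):
        """A HELIX record spanning residues 133-138 labels exactly those."""
        model = make_ideal_helix(10)
        ch = model.chains[0]
        for i, r in enumerate(ch.residues):
            r.seq_num = 130 + i
            r.ss = "helix" if 133 <= r.seq_num <= 138 else "other"
        p = tmp_path / "labels.pdb"
        write_model(model, p)
        again = read_model(p)
        labels = {r.seq_num: r.ss for r in again.residues()}
        for num in range(130, 140):
            assert (labels[num] == "helix") == (133 <= num <= 138)

    def test_sheet_records_round_trip(self, tmp_path, toy_model):
        p = tmp_path / "toy.pdb"
        write_model(toy_model, p)
        again = read_model(p)
        for orig, back in zip(toy_model.residues(), again.residues()):
            assert orig.ss == back.ss

    def test_missing_ca_warns(self, tmp_path):
        model = make_ideal_helix(6)
        model.chains[0].residues[2].atoms = [
            a for a in model.chains[0].residues[2].atoms if a.name != "CA"
        ]
        p = tmp_path / "gap.pdb"
        write_model(model, p)
        with pytest.warns(UserWarning, match="no CA"):
            again = read_model(p)
        assert again.n_residues() == 6  # residue kept


def test_toy_protein_simulation_round_trip(tmp_path, toy_model):
    """A simulated toy map survives MRC round trip and keeps its density."""
    gmap = simulate_map(SimulationSpec(model=toy_protein(), box=None))
    p = tmp_path / "toy.mrc"
    write_map(gmap, p)
    again = read_map(p)
    corr = np.corrcoef(gmap.data.ravel(), again.data.ravel())[0, 1]
    assert corr > 1.0 - 1e-9
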