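import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from paragrid import featurize as fz
from paragrid import structio as sio
from paragrid import surface as surf
from paragrid import synthdata as syn


class TestBalancedSample:
    def test_abundant_positives_capped_at_limit(self, abundant_complex):
        receptor, antigen, _ = abundant_complex
        cloud = surf.generate_surface(receptor)
        sampled = fz.balanced_sample(cloud, antigen, n=800, seed=0)
        assert len(sampled.positives) == 800
        assert len(sampled.negatives) == 800

    def test_scarce_positives_matched(self, abundant_complex):
        receptor, antigen, _ = abundant_complex
        cloud = surf.generate_surface(receptor)
        mask = fz.point_binding_mask(cloud, antigen)
        # restrict the cloud to exactly 500 positive-eligible points
        pos = np.flatnonzero(mask)[:500]
        keep = np.concatenate([pos, np.flatnonzero(~mask)])
        sub = surf.SurfaceCloud(
            points=cloud.points[keep], normals=cloud.normals[keep],
            parents=[cloud.parents[i] for i in keep],
            parent_atom=cloud.parent_atom[keep], density=cloud.density)
        sampled = fz.balanced_sample(sub, antigen, n=800, seed=0)
        assert len(sampled.positives) == 500
        assert len(sampled.negatives) == 500

    def test_deterministic_given_seed(self, toy_complex, toy_cloud):
        _, antigen, _ = toy_complex
        a = fz.balanced_sample(toy_cloud, antigen, seed=42)
        b = fz.balanced_sample(toy_cloud, antigen, seed=42)
        assert np.array_equal(a.positives, b.positives)
        assert np.array_equal(a.negatives, b.negatives)

    def test_zero_positives_yields_empty(self, toy_cloud):
        rid = sio.ResidueId("B", 1, "", "GLY")
        far = sio.Structure(
            [sio.Atom("C", np.array([0.0, 500.0, 0.0]), "CA", True, 0, 1, rid)],
            [rid], "antigen")
        sampled = fz.balanced_sample(toy_cloud, far)
        assert len(sampled.positives) == 0
        assert len(sampled.negatives) == 0

    @pytest.mark.parametrize("n", [10, 100, 800])
    def test_always_balanced(self, toy_complex, toy_cloud, n):
        _, antigen, _ = toy_complex
        sampled = fz.balanced_sample(toy_cloud, antigen, n=n, seed=1)
        assert len(sampled.positives) == len(sampled.negatives)


class TestAtomFeatures:
    def test_every_heavy_atom_has_22_channels(self, toy_complex, toy_features):
        receptor, _, _ = toy_complex
        assert toy_features.shape == (len(receptor.heavy_atoms()), fz.N_CHANNELS)
        assert fz.N_CHANNELS == 22

    def test_one_hot_class_for_classifiable_elements(self, toy_features):
        assert np.all(toy_features[:, :9].sum(axis=1) == 1.0)

    def test_alanine_carbonyl_oxygen(self, ala_dipeptide):
        feats = fz.compute_atom_features(ala_dipeptide)
        heavy = ala_dipeptide.heavy_atoms()
        i = [k for k, a in enumerate(heavy)
             if a.name == "O" and a.parent.number == 1][0]
        assert feats[i, 3] == 1.0  # class O
        assert feats[i, 15] == 1.0  # acceptor
        assert feats[i, 14] == 0.0  # not aromatic
        assert feats[i, 9] == 2.0  # sp2

    def test_backbone_nitrogen_is_donor(self, ala_dipeptide):
        feats = fz.compute_atom_features(ala_dipeptide)
        heavy = ala_dipeptide.heavy_atoms()
        # the N-terminal amine nitrogen donates hydrogen bonds
        i = [k for k, a in enumerate(heavy)
             if a.name == "N" and a.parent.number == 1][0]
        assert feats[i, 2] == 1.0  # class N
        assert feats[i, 16] == 1.0  # donor

    @pytest.mark.parametrize("element,index", [
        ("CL", 7), ("BR", 7), ("ZN", 8), ("FE", 8), ("SE", 6), ("P", 4),
    ])
    def test_halogen_and_metal_classes(self, element, index):
        onehot = fz.element_class_onehot(element)
        assert onehot[index] == 1.0
        assert onehot.sum() == 1.0

    def test_unclassifiable_element_all_zero(self):
        assert fz.element_class_onehot("XE").sum() == 0.0

    def test_pqr_changes_only_forcefield_channels(self, toy_complex, tmp_path):
        receptor, _, _ = toy_complex
        pqr = tmp_path / "toy.pqr"
        lines = []
        for i, a in enumerate(receptor.heavy_atoms(), 1):
            x, y, z = a.coords
            lines.append(
                f"ATOM {i} {a.name} {a.parent.resname} {a.parent.number} "
                f"{x:.3f} {y:.3f} {z:.3f} {0.123:.4f} {1.500:.4f}")
        pqr.write_text("\n".join(lines) + "\n")
        table = fz.read_pqr(pqr)
        ctx = fz.MolecularContext(receptor)
        base = fz.compute_atom_features(receptor, context=ctx)
        with_pqr = fz.compute_atom_features(receptor, pqr_amber=table,
                                            pqr_charmm=table, context=ctx)
        assert np.array_equal(base[:, :18], with_pqr[:, :18])
        assert np.all(with_pqr[:, 18] == pytest.approx(0.123))
        assert np.all(with_pqr[:, 19] == pytest.approx(1.5))
        assert not np.array_equal(base[:, 18:], with_pqr[:, 18:])


class TestLocalFrame:
    def test_axis_aligned_normal(self):
        R = fz.local_frame(np.array([0.0, 0.0, 1.0]))
        assert np.allclose(R[2], [0.0, 0.0, 1.0])
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)

    def test_random_normals_give_rotations(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = rng.standard_normal(3)
            n /= np.linalg.norm(n)
            R = fz.local_frame(n)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(R[2], n, atol=1e-9)

    def test_zero_normal_is_error(self):
        with pytest.raises(ValueError):
            fz.local_frame(np.zeros(3))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(v=st.tuples(*[st.floats(-10, 10, allow_nan=False) for _ in range(3)])
           .filter(lambda t: 1e-3 < np.linalg.norm(t) < 1e3))
    def test_frame_is_rotation_with_normal_third_row(self, v):
        n = np.asarray(v) / np.linalg.norm(v)
        R = fz.local_frame(n)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(R[2], n, atol=1e-9)


class TestVoxelize:
    def test_empty_neighborhood_all_zero(self, toy_complex, toy_features):
        receptor, _, _ = toy_complex
        grid = fz.voxelize(receptor, np.array([1e4, 1e4, 1e4]), np.eye(3),
                           toy_features)
        assert grid.tensor.shape == (41, 41, 41, 22)
        assert not grid.tensor.any()

    def test_single_atom_at_center(self):
        rid = sio.ResidueId("A", 1, "", "GLY")
        s = sio.Structure(
            [sio.Atom("C", np.zeros(3), "CA", True, 0, 1, rid)], [rid], "receptor")
        feats = np.zeros((1, 22))
        feats[0, 1] = 1.0  # carbon class
        grid = fz.voxelize(s, np.zeros(3), np.eye(3), feats)
        c = grid.tensor[..., 1]
        assert c[20, 20, 20] == 1.0
        assert c.sum() == 1.0

    def test_translation_invariance_bitwise(self, toy_complex, toy_cloud,
                                            toy_features):
        receptor, _, _ = toy_complex
        t = np.array([7.3, -2.1, 4.4])
        frame = fz.local_frame(toy_cloud.normals[0])
        g1 = fz.voxelize(receptor, toy_cloud.points[0], frame, toy_features)
        g2 = fz.voxelize(receptor.transformed(np.eye(3), t),
                         toy_cloud.points[0] + t, frame, toy_features)
        assert np.array_equal(g1.tensor, g2.tensor)

    def test_rotation_equivariance_off_boundary_atoms(self):
        # atoms placed at voxel centres, far from bin boundaries, so a
        # jointly rotated structure+frame must voxelize identically
        rng = np.random.default_rng(7)
        rid = sio.ResidueId("A", 1, "", "GLY")
        offsets = rng.integers(-15, 16, size=(30, 3)).astype(float)
        atoms = [sio.Atom("C", o, f"C{i}", True, 0, 1, rid)
                 for i, o in enumerate(offsets)]
        s = sio.Structure(atoms, [rid], "receptor")
        feats = np.tile(np.eye(22)[1], (30, 1))
        R = Rotation.random(random_state=11).as_matrix()
        t = np.array([3.0, -8.0, 1.0])
        g1 = fz.voxelize(s, np.zeros(3), np.eye(3), feats)
        g2 = fz.voxelize(s.transformed(R, t), t, np.eye(3) @ R.T, feats)
        assert np.array_equal(g1.tensor, g2.tensor)

    def test_all_atoms_within_20A_captured(self):
        rng = np.random.default_rng(9)
        rid = sio.ResidueId("A", 1, "", "GLY")
        coords = rng.uniform(-19.9, 19.9, size=(200, 3))
        coords = coords[np.linalg.norm(coords, axis=1) <= 20.0]
        atoms = [sio.Atom("C", c, f"C{i}", True, 0, 1, rid)
                 for i, c in enumerate(coords)]
        s = sio.Structure(atoms, [rid], "receptor")
        feats = np.tile(np.eye(22)[1], (len(atoms), 1))
        grid = fz.voxelize(s, np.zeros(3), np.eye(3), feats)
        assert grid.tensor[..., 1].sum() == len(atoms)

    def test_colocated_atoms_sum_channelwise(self):
        rid = sio.ResidueId("A", 1, "", "GLY")
        atoms = [sio.Atom("C", np.array([0.1, 0.0, 0.0]), "C1", True, 0, 1, rid),
                 sio.Atom("C", np.array([-0.1, 0.0, 0.0]), "C2", True, 0, 1, rid)]
        s = sio.Structure(atoms, [rid], "receptor")
        feats = np.tile(np.eye(22)[1], (2, 1))
        grid = fz.voxelize(s, np.zeros(3), np.eye(3), feats)
        assert grid.tensor[20, 20, 20, 1] == 2.0

    def test_even_size_rejected(self, toy_complex, toy_features):
        receptor, _, _ = toy_complex
        with pytest.raises(ValueError):
            fz.voxelize(receptor, np.zeros(3), np.eye(3), toy_features, size=40)


class TestRotate90:
    def _grid(self, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.random((9, 9, 9, 22)).astype(np.float32)
        return fz.FeatureGrid(tensor=t, center=np.zeros(3), frame=np.eye(3),
                              label=1)

    def test_four_turns_identity(self):
        g = self._grid()
        rotated = g.tensor
        for axis_plane in ((1, 2),):
            r = rotated
            for _ in range(4):
                r = np.rot90(r, 1, axes=axis_plane)
            assert np.array_equal(r, rotated)

    def test_channel_sums_conserved_and_label_kept(self):
        g = self._grid(3)
        out = fz.augment_rotate90(g, seed=12)
        assert np.allclose(out.tensor.sum(axis=(0, 1, 2)),
                           g.tensor.sum(axis=(0, 1, 2)))
        assert out.label == g.label

    def test_seed_reproducible(self):
        g = self._grid(4)
        a = fz.augment_rotate90(g, seed=7)
        b = fz.augment_rotate90(g, seed=7)
        assert np.array_equal(a.tensor, b.tensor)


class TestGridDataset:
    def test_extract_and_roundtrip(self, toy_complex, toy_cloud, toy_features,
                                   tmp_path):
        receptor, antigen, _ = toy_complex
        sampled = fz.balanced_sample(toy_cloud, antigen, n=20, seed=0)
        ds = fz.extract_grids(receptor, toy_cloud, sampled, toy_features,
                              size=9, structure_id="toy")
        assert len(ds) == 2 * len(sampled.positives)
        assert ds.X.shape[1:] == (9, 9, 9, 22)
        assert ds.y.sum() == len(sampled.positives)
        path = tmp_path / "grids.npz"
        ds.save(path)
        back = fz.GridDataset.load(path)
        assert np.array_equal(back.X, ds.X)
        assert np.array_equal(back.y, ds.y)
        assert back.manifest == ds.manifest
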