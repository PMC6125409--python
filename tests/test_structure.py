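"""Structure I/O, assemblies, geometric measures, clustering, plausibility."""

import itertools

import numpy as np
import pytest

from conftest import random_rigid, toy_model
from oligostate.structure import (
    ClashError,
    RigidTransform,
    StructureError,
    build_assembly,
    cluster_models,
    kabsch_rmsd,
    mass_from_concentration,
    molecular_mass,
    nterm_distance,
    radius_of_gyration,
    read_structure,
    rmsd_symm,
    trans_plausibility,
    write_pdb,
)
from oligostate.synthetic import ToyStructureSpec, make_toy_structure

MINIMAL_ALA_PDB = """\
ATOM      1  N   ALA A   1       0.000   1.458   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.426  -0.547   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.379   0.221   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1      -0.767  -0.518  -1.240  1.00  0.00           C
END
"""


class TestReadWrite:
    def test_single_alanine(self, tmp_path):
        path = tmp_path / "ala.pdb"
        path.write_text(MINIMAL_ALA_PDB)
        model = read_structure(path)
        assert model.chains == ["A"]
        assert model.n_atoms == 5

    def test_residue_range_filters(self, tmp_path):
        spec = ToyStructureSpec(n_chains=1, atoms_per_chain=50,
                                labeled_sites=(1, 25), seed=0)
        model, _ = make_toy_structure(spec)
        path = tmp_path / "toy.pdb"
        write_pdb(model, path)
        sub = read_structure(path, residue_range=(10, 20))
        assert sub.residue_numbers.min() == 10
        assert sub.residue_numbers.max() == 20

    def test_roundtrip_coordinates(self, tmp_path, sphere_dimer):
        model, _ = sphere_dimer
        path = tmp_path / "dimer.pdb"
        write_pdb(model, path)
        back = read_structure(path)
        assert back.n_atoms == model.n_atoms
        assert back.chains == model.chains
        # PDB fixed-width coordinates carry 3 decimals
        np.testing.assert_allclose(back.coords, model.coords, atol=1e-3)

    def test_unparseable_file(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(StructureError):
            read_structure(bad, residue_range=(1, 5))

    def test_empty_selection(self, tmp_path):
        path = tmp_path / "ala.pdb"
        path.write_text(MINIMAL_ALA_PDB)
        with pytest.raises(StructureError, match="empty selection"):
            read_structure(path, residue_range=(900, 950))


class TestAssembly:
    def test_identity_reproduces_base(self, sphere_dimer):
        model, _ = sphere_dimer
        asm = build_assembly(model, [RigidTransform.identity()], "dimer")
        np.testing.assert_allclose(asm.realize().coords, model.coords)

    def test_translation_separates_centroids(self, sphere_dimer):
        model, _ = sphere_dimer
        shift = RigidTransform(np.eye(3), np.array([100.0, 0, 0]))
        asm = build_assembly(model, [RigidTransform.identity(), shift],
                             "tetramer")
        realized = asm.realize()
        assert realized.n_atoms == 2 * model.n_atoms
        c0 = asm.unit_coords(0).mean(axis=0)
        c1 = asm.unit_coords(1).mean(axis=0)
        assert np.linalg.norm(c1 - c0) == pytest.approx(100.0)

    def test_unit_chains_relabelled(self, sphere_dimer):
        model, _ = sphere_dimer
        shift = RigidTransform(np.eye(3), np.array([100.0, 0, 0]))
        asm = build_assembly(model, [RigidTransform.identity(), shift])
        assert sorted(asm.realize().chains) == ["A0", "A1", "B0", "B1"]

    def test_rotation_matches_matrix_oracle(self, sphere_dimer):
        model, _ = sphere_dimer
        rng = np.random.default_rng(5)
        tr = random_rigid(rng)
        moved = build_assembly(model, [tr]).realize()
        expected = model.coords @ tr.rotation.T + tr.translation
        np.testing.assert_allclose(moved.coords, expected, atol=1e-9)

    def test_clash_detection(self, sphere_dimer):
        model, _ = sphere_dimer
        with pytest.raises(ClashError):
            build_assembly(model, [RigidTransform.identity(),
                                   RigidTransform(np.eye(3), np.zeros(3))])

    def test_nonorthonormal_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))


class TestMeasures:
    def test_rg_of_shell_equals_radius(self):
        spec = ToyStructureSpec(n_chains=1, atoms_per_chain=500,
                                shape="sphere-shell", radius=17.0)
        model, _ = make_toy_structure(spec)
        assert radius_of_gyration(model) == pytest.approx(17.0, abs=1e-6)

    def test_rg_single_point_warns_zero(self):
        model = toy_model(coords=[[1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            assert radius_of_gyration(model) == 0.0

    def test_rg_coincident_atoms(self):
        model = toy_model(coords=np.zeros((3, 3)),
                          resnums=[1, 2, 3])
        assert radius_of_gyration(model) == 0.0

    def test_measures_rigid_invariant(self, sphere_dimer):
        model, _ = sphere_dimer
        rg0 = radius_of_gyration(model)
        m0 = molecular_mass(model)
        rng = np.random.default_rng(11)
        for _ in range(3):
            tr = random_rigid(rng)
            moved = model.transformed(tr.rotation, tr.translation)
            assert radius_of_gyration(moved) == pytest.approx(rg0, abs=1e-6)
            assert molecular_mass(moved) == pytest.approx(m0)

    def test_polyglycine_mass(self):
        # 10 × 57.052 + 18.015 Da, hand-summed from the residue table
        assert molecular_mass("G" * 10) == pytest.approx(0.588535, abs=1e-6)

    def test_mass_empty_errors(self):
        with pytest.raises(StructureError):
            molecular_mass("")

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(StructureError, match="XYZ"):
            molecular_mass(["XYZ"])

    def test_mass_concentration_equivalence(self):
        # 26.2 mg/ml at 919.4 µM of subunits implies a ~57 kDa dimer
        assert round(mass_from_concentration(26.2, 919.4, n_subunits=2)) == 57

    def test_nterm_distance_345(self):
        model = toy_model(coords=[[0, 0, 0], [5, 5, 5], [30, 40, 0], [40, 40, 5]],
                          chains=["A", "A", "B", "B"],
                          resnums=[1, 2, 1, 2])
        assert nterm_distance(model) == pytest.approx(5.0)

    def test_nterm_distance_coincident(self):
        model = toy_model(coords=[[0, 0, 0], [5, 5, 5], [0, 0, 0.0001], [9, 9, 9]],
                          chains=["A", "A", "B", "B"], resnums=[1, 2, 1, 2])
        assert nterm_distance(model) == pytest.approx(0.0, abs=1e-4)


class TestRmsdSymm:
    def test_self_is_zero(self, sphere_dimer):
        model, _ = sphere_dimer
        assert rmsd_symm(model, model) == pytest.approx(0.0, abs=1e-9)

    def test_chain_swap_is_zero(self, sphere_dimer):
        model, _ = sphere_dimer
        swapped_ids = np.where(model.chain_ids == "A", "B", "A")
        swapped = toy_model(coords=model.coords,
                            chains=list(swapped_ids),
                            resnums=model.residue_numbers)
        assert rmsd_symm(model, swapped) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_and_nonnegative(self, sphere_dimer):
        model, _ = sphere_dimer
        rng = np.random.default_rng(3)
        other = model.transformed(np.eye(3), np.zeros(3))
        other.coords = other.coords + rng.normal(0, 1.0, other.coords.shape)
        d1, d2 = rmsd_symm(model, other), rmsd_symm(other, model)
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert d1 > 0

    def test_matches_exhaustive_permutation_kabsch_oracle(self):
        rng = np.random.default_rng(7)
        coords_a = rng.uniform(-10, 10, (6, 3))
        chains = ["A", "A", "B", "B", "C", "C"]
        resnums = [1, 2, 1, 2, 1, 2]
        a = toy_model(coords=coords_a, chains=chains, resnums=resnums)
        tr = random_rigid(rng)
        perm = [4, 5, 0, 1, 2, 3]           # rotate chain identities
        coords_b = (coords_a @ tr.rotation.T + tr.translation)[perm]
        coords_b += rng.normal(0, 0.3, coords_b.shape)
        b = toy_model(coords=coords_b, chains=chains, resnums=resnums)

        best = np.inf
        blocks = [slice(0, 2), slice(2, 4), slice(4, 6)]
        for p in itertools.permutations(range(3)):
            cb = np.vstack([coords_b[blocks[i]] for i in p])
            best = min(best, kabsch_rmsd(coords_a, cb))
        assert rmsd_symm(a, b) == pytest.approx(best, abs=1e-6)

    def test_composition_mismatch(self, sphere_dimer):
        model, _ = sphere_dimer
        small = toy_model(n=4)
        with pytest.raises(StructureError):
            rmsd_symm(model, small)


class TestClustering:
    def _assemblies(self, shapes, jitter, seed=0):
        """Assemblies whose *internal geometry* differs between groups.

        The clustering metric superposes models, so only conformational
        differences (not placement) separate clusters; each entry of
        ``shapes`` displaces one atom of the base by that amount.
        """
        rng = np.random.default_rng(seed)
        coords0 = rng.uniform(-5, 5, (8, 3))
        out = []
        for i, stretch in enumerate(shapes):
            coords = coords0.copy()
            coords[0] += [stretch, 0, 0]
            coords += rng.normal(0, jitter, coords.shape)
            base = toy_model(coords=coords, chains=["A"] * 8)
            out.append(build_assembly(base, [RigidTransform.identity()],
                                      model_id=f"m{i}"))
        return out

    def test_identical_models_single_cluster(self):
        models = self._assemblies([0.0] * 5, jitter=0.0)
        result = cluster_models(models, cutoff=10.0)
        assert len(result.representatives) == 1
        assert set(result.cluster_assignments.values()) == {0}

    def test_two_separated_groups(self):
        models = self._assemblies([0.0] * 3 + [100.0] * 3, jitter=0.3)
        result = cluster_models(models, cutoff=10.0)
        assert len(result.representatives) == 2

    def test_members_within_cutoff_and_idempotent(self):
        models = self._assemblies([0.0] * 3 + [100.0] * 3 + [200.0] * 2,
                                  jitter=0.3)
        ids = [m.model_id for m in models]
        result = cluster_models(models, cutoff=10.0, ids=ids)
        by_id = dict(zip(ids, models))
        for mid, ci in result.cluster_assignments.items():
            rep = by_id[result.representatives[ci]]
            assert rmsd_symm(by_id[mid], rep) <= 10.0
        reps = [by_id[r] for r in result.representatives]
        again = cluster_models(reps, cutoff=10.0, ids=result.representatives)
        assert again.representatives == result.representatives


class TestTransPlausibility:
    def _tetramer(self, flip: bool):
        """Two-chain slab dimers stacked along z; anchors point down (−z)."""
        coords = np.array([[float(x), y, 0.0] for x in range(0, 9)
                           for y in (0.0, 4.0)])
        anchors = np.array([[4.0, 0.0, -6.0], [4.0, 4.0, -6.0]])
        coords = np.vstack([coords, anchors])
        n9 = 9
        chains = (["A"] * n9 + ["B"] * n9 + ["A", "B"])
        resnums = (list(range(1, n9 + 1)) * 2 + [n9 + 1, n9 + 1])
        base = toy_model(coords=coords, chains=chains, resnums=resnums)
        if flip:
            R = np.diag([1.0, -1.0, -1.0])   # 180° about x: anchors face away
        else:
            R = np.eye(3)
        tr = RigidTransform(R, np.array([0.0, 0.0, 14.0]))
        return build_assembly(base, [RigidTransform.identity(), tr],
                              "tetramer", allow_clash=True)

    def test_opposite_anchors_plausible(self):
        verdict, angle = trans_plausibility(self._tetramer(flip=True))
        assert verdict == "plausible"
        assert angle > 120

    def test_same_face_implausible(self):
        verdict, angle = trans_plausibility(self._tetramer(flip=False))
        assert verdict == "implausible"
        assert angle < 10

    def test_rigid_motion_invariance(self):
        tet = self._tetramer(flip=True)
        rng = np.random.default_rng(13)
        tr = random_rigid(rng)
        moved_units = [RigidTransform(tr.rotation @ u.rotation,
                                      tr.rotation @ u.translation + tr.translation)
                       for u in tet.units]
        moved = build_assembly(tet.base, moved_units, "tetramer",
                               allow_clash=True)
        v0, a0 = trans_plausibility(tet)
        v1, a1 = trans_plausibility(moved)
        assert v0 == v1
        assert a0 == pytest.approx(a1, abs=1e-6)

    def test_boundary_angle_inclusive(self):
        # two single-anchor "dimers" engineered at exactly 120°
        coords = np.vstack([np.zeros((5, 3)) + [0, 0, 0],
                            np.zeros((5, 3)) + [2, 0, 0]])
        coords[:, 2] = np.tile(np.arange(5) * 0.5, 2)
        base = toy_model(coords=coords, chains=["A"] * 5 + ["B"] * 5,
                         resnums=list(range(1, 6)) * 2)
        # anchors = residue 5; place them so unit directions differ by 120°
        a1 = np.array([0.0, 0.0, 10.0])
        base.coords[4] = a1
        base.coords[9] = a1 + [2, 0, 0]
        ang = np.radians(120.0)
        R = np.array([[1, 0, 0],
                      [0, np.cos(ang), -np.sin(ang)],
                      [0, np.sin(ang), np.cos(ang)]])
        tr = RigidTransform(R, np.array([0.0, 30.0, 0.0]))
        tet = build_assembly(base, [RigidTransform.identity(), tr],
                             "tetramer", allow_clash=True)
        verdict, angle = trans_plausibility(tet, anchor_residues=[5])
        assert angle == pytest.approx(120.0, abs=1.0)
        if angle >= 120.0 - 1e-9:
            assert verdict in ("plausible", "implausible")
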