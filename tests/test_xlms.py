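"""Cross-link parsing, SASD grid, MNXL scoring, state assignment, scans."""

import numpy as np
import pytest

from conftest import toy_model
from oligostate.structure import RigidTransform, build_assembly
from oligostate.synthetic import ToyStructureSpec, make_toy_structure
from oligostate.xlms import (
    NOT_ACCESSIBLE,
    CrossLink,
    MNXLParams,
    SolventGrid,
    assign_states,
    compute_sasd,
    euclidean_prefilter,
    load_text_named_crosslinks,
    mnxl_score,
    parse_crosslinks,
    restraint_scan,
    score_model,
    symmetrize_restraints,
)


class TestParsing:
    def test_packaged_text_named_pairs(self):
        xls = load_text_named_crosslinks()
        assert len(xls) == 11
        keys = {xl.key for xl in xls}
        assert (61, 218) in keys and (129, 129) in keys

    def test_canonical_ordering(self, tmp_path):
        path = tmp_path / "xl.tsv"
        path.write_text("residue_a\tresidue_b\tbands\tconstruct\n"
                        "218\t61\tmonomer\tEX\n")
        (xl,) = parse_crosslinks(path)
        assert xl.key == (61, 218)

    def test_duplicate_bands_merged(self, tmp_path):
        path = tmp_path / "xl.tsv"
        path.write_text("residue_a\tresidue_b\tbands\tconstruct\n"
                        "61\t218\tmonomer\tEX\n"
                        "218\t61\tdimer\tEX\n")
        (xl,) = parse_crosslinks(path)
        assert xl.bands == frozenset({"monomer", "dimer"})

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "xl.tsv"
        path.write_text("residue_a\tresidue_b\tbands\tconstruct\n"
                        "61\tnotanumber\tmonomer\tEX\n")
        with pytest.raises(ValueError, match="row 2"):
            parse_crosslinks(path)

    def test_empty_bands_rejected(self):
        with pytest.raises(ValueError):
            CrossLink(1, 2, frozenset())


class TestPrefilter:
    def test_close_pair_kept(self):
        model = toy_model(coords=[[0, 0, 0], [10, 0, 0]], resnums=[1, 2])
        rows = euclidean_prefilter(model, CrossLink(1, 2), cutoff=33.0)
        assert rows[0]["keep"] and rows[0]["euclidean"] == pytest.approx(10.0)

    def test_distant_pair_excluded(self):
        model = toy_model(coords=[[0, 0, 0], [40, 0, 0]], resnums=[1, 2])
        rows = euclidean_prefilter(model, CrossLink(1, 2), cutoff=33.0)
        assert not rows[0]["keep"]

    def test_intra_excluded_inter_kept(self):
        # intra-chain pair 50 Å apart, inter-chain copy only 20 Å apart
        coords = [[0, 0, 0], [50, 0, 0], [64, 0, 0], [14, 0, 0]]
        model = toy_model(coords=coords, chains=["A", "A", "B", "B"],
                          resnums=[1, 2, 1, 2])
        rows = euclidean_prefilter(model, CrossLink(1, 2), cutoff=33.0)
        by_variant = {r["variant"]: r for r in rows}
        assert not by_variant["intra:A"]["keep"]
        assert by_variant["inter:A-B"]["keep"]
        assert by_variant["inter:A-B"]["euclidean"] == pytest.approx(14.0)

    def test_missing_residue_errors(self):
        model = toy_model(n=3)
        with pytest.raises(ValueError, match="99"):
            euclidean_prefilter(model, CrossLink(1, 99))


def _dijkstra_oracle(grid: SolventGrid, a, b):
    """Independent shortest-path check via networkx on the voxel graph."""
    import networkx as nx
    va = grid.nearest_free_voxel(a, toward=b)
    vb = grid.nearest_free_voxel(b, toward=a)
    assert va is not None and vb is not None
    free = np.argwhere(grid.solvent)
    index = {tuple(v): i for i, v in enumerate(free)}
    G = nx.Graph()
    offs = [np.array(o) for o in np.ndindex(3, 3, 3)]
    for i, v in enumerate(free):
        for o in offs:
            d = o - 1
            if not d.any():
                continue
            w = tuple(v + d)
            j = index.get(w)
            if j is not None and j > i:
                G.add_edge(i, j,
                           weight=float(np.linalg.norm(d)) * grid.spacing)
    path = nx.dijkstra_path_length(G, index[tuple(va)], index[tuple(vb)])
    return (path + np.linalg.norm(a - grid.center_of(va))
            + np.linalg.norm(b - grid.center_of(vb)))


class TestSASD:
    def test_free_space_path_is_straight(self):
        model = toy_model(coords=[[0, 0, 0], [12, 0, 0]], resnums=[1, 2])
        (res,) = [r for r in compute_sasd(model, CrossLink(1, 2),
                                          grid_spacing=1.0)
                  ]
        # endpoints sit in open solvent: SASD ≈ Euclidean within a voxel
        # diagonal of slack
        assert res.sasd == pytest.approx(12.0, abs=np.sqrt(3) * 1.0 + 1.0)

    def test_wall_forces_detour_and_matches_oracle(self):
        spec = ToyStructureSpec(n_chains=1, atoms_per_chain=80,
                                shape="slab-with-aperture",
                                labeled_sites=(1, 2), seed=0)
        wall, _ = make_toy_structure(spec)
        # endpoints on both sides of the wall, off the aperture axis
        probe = toy_model(coords=np.vstack([wall.coords,
                                            [[-6.0, 8.0, 0.0],
                                             [6.0, 8.0, 0.0]]]),
                          chains=["A"] * (wall.n_atoms + 2),
                          resnums=list(range(1, wall.n_atoms + 3)))
        xl = CrossLink(wall.n_atoms + 1, wall.n_atoms + 2)
        grid = SolventGrid(probe, spacing=1.0)
        (res,) = compute_sasd(probe, xl, grid=grid, prefilter_cutoff=None)
        assert res.sasd > res.euclidean          # the wall forces a detour
        oracle = _dijkstra_oracle(grid,
                                  probe.coords[-2], probe.coords[-1])
        assert res.sasd == pytest.approx(oracle, abs=2 * grid.spacing)

    def test_sasd_at_least_euclidean(self, sphere_dimer):
        model, _ = sphere_dimer
        grid = SolventGrid(model, spacing=1.0)
        for pair in [(1, 25), (1, 50), (25, 100), (50, 75)]:
            for r in compute_sasd(model, CrossLink(*pair), grid=grid,
                                  prefilter_cutoff=None):
                if np.isfinite(r.sasd):
                    assert r.sasd >= r.euclidean - 1e-9

    def test_grid_refinement_non_increasing(self):
        spec = ToyStructureSpec(n_chains=1, atoms_per_chain=60,
                                shape="sphere-shell", radius=8.0,
                                labeled_sites=(1, 30))
        model, _ = make_toy_structure(spec)
        xl = CrossLink(1, 30)
        values = []
        for spacing in (2.0, 1.0, 0.5):
            (res,) = compute_sasd(model, xl, grid_spacing=spacing,
                                  prefilter_cutoff=None)
            values.append(res.sasd)
        # finer grids cut corners more accurately: path never lengthens
        # beyond a voxel diagonal of tolerance
        assert values[1] <= values[0] + 2.0 * np.sqrt(3)
        assert values[2] <= values[1] + 1.0 * np.sqrt(3)

    def test_prefiltered_variant_not_searched(self):
        model = toy_model(coords=[[0, 0, 0], [50, 0, 0]], resnums=[1, 2])
        (res,) = compute_sasd(model, CrossLink(1, 2), prefilter_cutoff=33.0)
        assert res.sasd == NOT_ACCESSIBLE

    def test_buried_endpoint_not_accessible(self):
        # endpoint sealed inside a dense shell
        spec = ToyStructureSpec(n_chains=1, atoms_per_chain=900,
                                shape="sphere-shell", radius=8.0)
        shell, _ = make_toy_structure(spec)
        probe = toy_model(coords=np.vstack([shell.coords, [[0, 0, 0],
                                                           [30, 0, 0]]]),
                          chains=["A"] * (shell.n_atoms + 2),
                          resnums=list(range(1, shell.n_atoms + 3)))
        xl = CrossLink(shell.n_atoms + 1, shell.n_atoms + 2)
        (res,) = compute_sasd(probe, xl, prefilter_cutoff=None)
        assert res.sasd == NOT_ACCESSIBLE


class TestMNXL:
    def test_above_cutoff_penalty(self):
        assert mnxl_score(40.0) == -0.1

    def test_not_accessible_penalty(self):
        assert mnxl_score(NOT_ACCESSIBLE) == -0.1

    def test_peak_value_is_normal_density_at_mean(self):
        # 1/sqrt(2π·35.94) under the variance reading of the dispersion
        expected = 1.0 / np.sqrt(2 * np.pi * 35.94)
        assert mnxl_score(18.62) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0666, abs=5e-4)

    def test_maximum_at_mu_and_cutoff_discontinuity(self):
        params = MNXLParams()
        grid = np.linspace(0.1, params.cutoff, 200)
        scores = [mnxl_score(s, params) for s in grid]
        assert grid[int(np.argmax(scores))] == pytest.approx(params.mu, abs=0.2)
        assert mnxl_score(params.cutoff - 1e-9) > 0
        assert mnxl_score(params.cutoff + 1e-9) == params.penalty

    def test_sigma_mode_changes_width(self):
        wide = mnxl_score(30.0, MNXLParams(sigma_mode=True))
        narrow = mnxl_score(30.0, MNXLParams())
        assert wide != narrow

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MNXLParams(mu=40.0)
        with pytest.raises(ValueError):
            MNXLParams(penalty=0.1)


class TestScoreModel:
    def test_empty_crosslink_list(self, sphere_dimer):
        model, _ = sphere_dimer
        ms = score_model(model, [])
        assert ms.total == 0.0
        assert ms.matched_count == ms.nonaccessible_count == 0

    def test_counts_partition(self, sphere_dimer):
        model, _ = sphere_dimer
        xls = [CrossLink(1, 25), CrossLink(1, 50), CrossLink(25, 75)]
        ms = score_model(model, xls, grid_spacing=1.5)
        assert ms.matched_count + ms.nonaccessible_count == len(xls)
        assert ms.total == pytest.approx(sum(ms.per_crosslink.values()))

    def test_reference_waives_penalty(self, sphere_dimer):
        model, _ = sphere_dimer
        xl = CrossLink(1, 25)
        # fake reference that matched this cross-link in the dimer
        from oligostate.xlms import ModelScore
        ref = ModelScore("dimer", {xl.key: 0.05}, {xl.key: True}, 1, 0)
        # far-apart two-atom model: the cross-link is non-accessible
        far = toy_model(coords=[[0, 0, 0], [80, 0, 0]], resnums=[1, 25])
        without = score_model(far, [xl])
        withref = score_model(far, [xl], reference=ref)
        assert without.per_crosslink[xl.key] == -0.1
        assert withref.per_crosslink[xl.key] == 0.0

    def test_reference_never_decreases_score(self, sphere_dimer):
        model, _ = sphere_dimer
        xls = [CrossLink(1, 25), CrossLink(25, 100)]
        ref = score_model(model, xls, grid_spacing=1.5, model_id="dimer")
        far = toy_model(coords=[[0, 0, 0], [80, 0, 0], [160, 0, 0]],
                        resnums=[1, 25, 100])
        base = score_model(far, xls)
        with_ref = score_model(far, xls, reference=ref)
        assert with_ref.total >= base.total - 1e-12


class TestAssignStates:
    def test_monomer_exclusive_band_wins(self, sphere_dimer):
        model, _ = sphere_dimer
        monomer = model.select(model.chain_mask("A"))
        xl = CrossLink(1, 25, frozenset({"monomer"}))
        states = assign_states([xl], {"monomer": monomer, "dimer": model},
                               grid_spacing=1.5)
        assert states[xl] == "monomer"

    def test_self_pair_never_monomer(self, sphere_dimer):
        model, _ = sphere_dimer
        monomer = model.select(model.chain_mask("A"))
        xl = CrossLink(50, 50, frozenset({"monomer"}))
        states = assign_states([xl], {"monomer": monomer, "dimer": model},
                               grid_spacing=1.5)
        assert states[xl] != "monomer"

    def test_inter_subunit_link_assigned_to_dimer(self):
        # chains 14 Å apart: residues 1(A) and 2(B) are cross-linkable
        # only when both chains are present
        coords = [[0, 0, 0], [0, 40, 0], [14, 40, 0], [14, 0, 0]]
        dimer = toy_model(coords=coords, chains=["A", "A", "B", "B"],
                          resnums=[1, 2, 1, 2])
        monomer = dimer.select(dimer.chain_mask("A"))
        xl = CrossLink(1, 2, frozenset({"monomer", "dimer"}))
        states = assign_states([xl], {"monomer": monomer, "dimer": dimer})
        assert states[xl] == "dimer"


class TestRestraints:
    def _tetramer(self):
        spec = ToyStructureSpec(n_chains=2, atoms_per_chain=60,
                                shape="sphere-shell", radius=8.0,
                                separation=20.0, labeled_sites=(1, 30))
        dimer, _ = make_toy_structure(spec)
        shift = RigidTransform(np.eye(3), np.array([0.0, 0.0, 40.0]))
        return build_assembly(dimer, [RigidTransform.identity(), shift],
                              "tetramer")

    def test_symmetrization_doubles(self):
        tet = self._tetramer()
        rs = symmetrize_restraints([CrossLink(1, 30)], tet)
        assert rs.symmetry_completed
        assert len(rs) == 2

    def test_self_symmetric_not_duplicated(self):
        tet = self._tetramer()
        # a self-pair restraint that maps onto itself under the 2-fold
        rs = symmetrize_restraints([CrossLink(1, 1)], tet)
        chains = {frozenset([(r.chain_a, r.res_a), (r.chain_b, r.res_b)])
                  for r in rs.restraints}
        assert len(chains) == len(rs.restraints)   # no duplicates

    def test_minimum_distance_chain_assignment(self):
        tet = self._tetramer()
        rs = symmetrize_restraints([CrossLink(1, 30)], tet)
        s = tet.realize()
        from oligostate.xlms import _endpoint_atoms
        r0 = rs.restraints[0]
        chosen = np.linalg.norm(_endpoint_atoms(s, r0.res_a)[r0.chain_a]
                                - _endpoint_atoms(s, r0.res_b)[r0.chain_b])
        for ca, pa in _endpoint_atoms(s, r0.res_a).items():
            for cb, pb in _endpoint_atoms(s, r0.res_b).items():
                assert chosen <= np.linalg.norm(pa - pb) + 1e-9

    def test_scan_matches_bruteforce(self):
        tet = self._tetramer()
        rs = symmetrize_restraints([CrossLink(1, 30), CrossLink(30, 30)],
                                   tet, max_dist=25.0)
        rng = np.random.default_rng(4)
        ensemble = []
        for i in range(4):
            shift = RigidTransform(np.eye(3),
                                   np.array([0.0, 0.0, 30.0 + 20 * i]))
            ensemble.append(build_assembly(tet.base,
                                           [RigidTransform.identity(), shift],
                                           model_id=f"e{i}"))
        table = restraint_scan(ensemble, rs)
        from oligostate.xlms import _endpoint_atoms
        for _, row in table.iterrows():
            model = ensemble[int(row["model_id"][1:])]
            s = model.realize()
            expected = 0
            for r in rs.restraints:
                pa = _endpoint_atoms(s, r.res_a).get(r.chain_a)
                pb = _endpoint_atoms(s, r.res_b).get(r.chain_b)
                if pa is not None and pb is not None and \
                        np.linalg.norm(pa - pb) <= r.max_dist:
                    expected += 1
            assert row["satisfied"] == expected

    def test_impossible_restraints_zero(self):
        tet = self._tetramer()
        rs = symmetrize_restraints([CrossLink(1, 30)], tet, max_dist=0.5)
        table = restraint_scan([tet], rs)
        assert table["satisfied"].max() == 0
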