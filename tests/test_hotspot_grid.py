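import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pocketdyn import (
    CagePocketConfig,
    HotspotParams,
    ProbeScorer,
    RaySet,
    ResidueSelection,
    build_site_grid,
    classify_buried,
    consensus_filter,
    contact_well_scorer,
    designate_hotspots,
    ligand_com,
    make_cage_pocket,
    map_ensemble,
    prune_clashes,
    restrict_to_site,
    score_probes,
    select_top_hotspots,
)
from pocketdyn._elements import vdw_radii
from pocketdyn.errors import UnknownElementError
from pocketdyn.hotspot_grid import _ray_occluded
from pocketdyn.structure_io import Structure

from _oracles import (
    dense_occlusion_fraction,
    hotspot_oracle,
    neighbor_count_oracle,
)
from conftest import point_ligand


def atoms_structure(coords, elements=None):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = np.array(elements if elements is not None else ["C"] * n, dtype="U2")
    return Structure(
        chain_id=np.full(n, "A"),
        res_id=np.arange(1, n + 1),
        ins_code=np.full(n, ""),
        res_name=np.full(n, "UNK"),
        atom_name=np.full(n, "X"),
        element=elements,
        coords=coords,
        hetero=np.full(n, False),
    )


class TestRaySet:
    def test_icosahedron_unit_and_centrally_symmetric(self):
        rays = RaySet.icosahedron()
        assert rays.n_rays == 12
        np.testing.assert_allclose(
            np.linalg.norm(rays.directions, axis=1), 1.0, atol=1e-12
        )
        # closed under negation
        for d in rays.directions:
            assert np.min(np.linalg.norm(rays.directions + d, axis=1)) < 1e-10


class TestLigandCom:
    def test_single_atom(self):
        s = atoms_structure([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(ligand_com(s), [1.0, 2.0, 3.0])

    def test_two_equal_masses_at_origin(self):
        s = atoms_structure([[1, 0, 0], [-1, 0, 0]])
        np.testing.assert_allclose(ligand_com(s), 0.0, atol=1e-12)

    def test_mixed_elements_hand_weighted_mean(self):
        coords = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3], [1, 1, 1]], dtype=float
        )
        elements = ["C", "N", "O", "S", "H"]
        masses = np.array([12.011, 14.007, 15.999, 32.06, 1.008])
        expected = (coords * masses[:, None]).sum(axis=0) / masses.sum()
        s = atoms_structure(coords, elements)
        np.testing.assert_allclose(ligand_com(s), expected, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ligand_com(atoms_structure(np.zeros((0, 3))))


class TestBuildGrid:
    @pytest.mark.parametrize(
        "extent,expected", [(1.0, 27), (0.5, 1), (8.0, 17**3)]
    )
    def test_lattice_counts(self, extent, expected):
        g = build_site_grid(np.zeros(3), 1.0, extent)
        assert g.n_points == expected
        # position identity: origin + spacing * lattice
        np.testing.assert_allclose(g.positions, g.lattice.astype(float), atol=0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_site_grid(np.zeros(3), 0.0, 1.0)
        with pytest.raises(ValueError):
            build_site_grid(np.zeros(3), 1.0, -1.0)


class TestPruneClashes:
    def test_no_atoms_nothing_pruned(self):
        g = build_site_grid(np.zeros(3), 1.0, 2.0)
        g = prune_clashes(g, atoms_structure(np.zeros((0, 3))))
        assert not g.pruned.any()

    def test_single_carbon_bondi_sphere(self):
        g = build_site_grid(np.zeros(3), 1.0, 4.0)
        g = prune_clashes(g, atoms_structure([[0.0, 0.0, 0.0]]), margin=1.5)
        # Bondi C radius 1.70 + 1.5 margin
        d = np.linalg.norm(g.positions, axis=1)
        np.testing.assert_array_equal(g.pruned, d < 3.2 + 1e-12)

    def test_distant_atom_changes_nothing(self):
        g = build_site_grid(np.zeros(3), 1.0, 2.0)
        g = prune_clashes(g, atoms_structure([[12.0, 0.0, 0.0]]))
        assert not g.pruned.any()

    def test_unknown_element_raises(self):
        g = build_site_grid(np.zeros(3), 1.0, 1.0)
        with pytest.raises(UnknownElementError, match="Xx"):
            prune_clashes(g, atoms_structure([[0, 0, 0]], ["Xx"]))


class TestRestrictToSite:
    def test_sphere_lattice_count_123(self):
        g = build_site_grid(np.zeros(3), 1.0, 5.0)
        g = restrict_to_site(g, np.zeros((1, 3)), cutoff=3.0)
        assert int(g.in_site.sum()) == 123
        # brute-force lattice-in-sphere count
        brute = int((np.linalg.norm(g.positions, axis=1) <= 3.0).sum())
        assert int(g.in_site.sum()) == brute

    def test_cutoff_below_spacing_from_offset_ligand(self):
        g = build_site_grid(np.zeros(3), 1.0, 2.0)
        g = restrict_to_site(g, np.array([[0.5, 0.5, 0.5]]), cutoff=0.5)
        assert int(g.in_site.sum()) == 0

    def test_two_distant_atoms_union_of_spheres(self):
        g = build_site_grid(np.zeros(3), 1.0, 8.0)
        lig = np.array([[-4.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        g = restrict_to_site(g, lig, cutoff=2.0)
        pos = g.positions
        in_a = np.linalg.norm(pos - lig[0], axis=1) <= 2.0
        in_b = np.linalg.norm(pos - lig[1], axis=1) <= 2.0
        np.testing.assert_array_equal(g.in_site, in_a | in_b)

    def test_pruned_points_never_in_site(self):
        g = build_site_grid(np.zeros(3), 1.0, 3.0)
        g = prune_clashes(g, atoms_structure([[0.0, 0.0, 0.0]]))
        g = restrict_to_site(g, np.zeros((1, 3)), cutoff=3.0)
        assert not (g.in_site & g.pruned).any()


def site_everywhere(g):
    """Mark all unpruned points in-site (cage tests use the whole interior)."""
    from dataclasses import replace

    return replace(g, in_site=~g.pruned)


class TestBuriedness:
    def test_closed_cage_center_buried(self):
        cage, _, _ = make_cage_pocket(CagePocketConfig(seed=1))
        g = site_everywhere(build_site_grid(np.zeros(3), 1.0, 2.0))
        g = classify_buried(g, cage)
        center = np.all(g.lattice == 0, axis=1)
        assert g.occluded[center][0]
        assert g.buried[center][0]
        # deep interior: every point occluded, so interiors have full support
        assert g.buried.all()

    def test_point_far_from_any_atom_not_buried(self):
        cage, _, _ = make_cage_pocket(CagePocketConfig(seed=1))
        far = build_site_grid(np.array([100.0, 0.0, 0.0]), 1.0, 1.0)
        far = site_everywhere(far)
        far = classify_buried(far, cage)
        assert not far.occluded.any()
        assert not far.buried.any()

    @pytest.mark.parametrize("seed", range(4))
    def test_aperture_decision_matches_dense_oracle(self, seed):
        """12-ray occlusion agrees with a 2000-direction oracle away from
        the 10/12 quota boundary band."""
        rng = np.random.default_rng(100 + seed)
        rays = RaySet.icosahedron(10.0)
        for half_angle in (0.0, 15.0, 80.0, 100.0):
            axis = rng.normal(size=3)
            cage, _, _ = make_cage_pocket(
                CagePocketConfig(
                    seed=seed, aperture_half_angle=half_angle, aperture_axis=axis
                )
            )
            radii = vdw_radii(cage.element)
            frac = dense_occlusion_fraction(np.zeros(3), cage.coords, radii)
            if 9.5 / 12 <= frac <= 10.5 / 12:
                continue  # boundary band: decision may legitimately differ
            impl = _ray_occluded(
                np.zeros((1, 3)), rays, cage.coords, radii, hit_quota=10
            )[0]
            assert impl == (frac >= 10.0 / 12.0)

    def test_support_pass_strips_isolated_occluded_point(self):
        # only the centre point is in-site: occluded but with zero
        # occluded neighbours, so it cannot be buried
        cage, _, _ = make_cage_pocket(CagePocketConfig(seed=2))
        g = build_site_grid(np.zeros(3), 1.0, 2.0)
        in_site = np.all(g.lattice == 0, axis=1)
        from dataclasses import replace

        g = replace(g, in_site=in_site)
        g = classify_buried(g, cage)
        assert g.occluded[in_site][0]
        assert not g.buried.any()

    def test_far_atoms_change_no_flags(self):
        cage, _, _ = make_cage_pocket(CagePocketConfig(seed=3))
        g0 = site_everywhere(build_site_grid(np.zeros(3), 1.0, 2.0))
        g1 = classify_buried(g0, cage)
        # add atoms beyond max vdW + margin + ray length from every point
        far = atoms_structure(np.array([[40.0, 0, 0], [0, -35.0, 0]]))
        combined = atoms_structure(
            np.vstack([cage.coords, far.coords]),
            list(cage.element) + list(far.element),
        )
        g2 = classify_buried(g0, combined)
        np.testing.assert_array_equal(g1.occluded, g2.occluded)
        np.testing.assert_array_equal(g1.buried, g2.buried)


class TestScoreProbes:
    def _buried_grid(self, extent=1.0):
        from dataclasses import replace

        g = build_site_grid(np.zeros(3), 1.0, extent)
        return replace(
            g,
            in_site=np.ones(g.n_points, dtype=bool),
            buried=np.ones(g.n_points, dtype=bool),
        )

    def test_zero_scorer(self):
        g = self._buried_grid()
        scorer = ProbeScorer("zero", lambda p, c, e: 0.0)
        g = score_probes(g, atoms_structure([[5.0, 0, 0]]), scorer)
        assert np.all(g.scores[g.buried] == 0.0)

    @pytest.mark.parametrize(
        "d,expected",
        [(2.0, 0.0), (2.5, 0.0), (3.0, 0.5), (3.5, 1.0), (4.0, 1.0),
         (4.5, 1.0), (5.0, 1.0 / 1.5), (6.0, 0.0), (7.0, 0.0)],
    )
    def test_contact_well_closed_form(self, d, expected):
        scorer = contact_well_scorer()
        val = scorer.fn(np.zeros(3), np.array([[d, 0.0, 0.0]]), ["C"])
        assert val == pytest.approx(expected, abs=1e-12)

    def test_contact_well_ignores_hydrogens(self):
        scorer = contact_well_scorer()
        val = scorer.fn(
            np.zeros(3), np.array([[4.0, 0, 0], [4.0, 0, 0]]), ["H", "C"]
        )
        assert val == pytest.approx(1.0)

    def test_neighbor_count_scorer_matches_brute_force(self, rng):
        coords = rng.normal(scale=4.0, size=(40, 3))
        scorer = ProbeScorer(
            "count45",
            lambda p, c, e: float((np.linalg.norm(c - p, axis=1) <= 4.5).sum()),
        )
        g = self._buried_grid(extent=2.0)
        g = score_probes(g, atoms_structure(coords), scorer)
        for i in range(g.n_points):
            expected = sum(
                1 for c in coords if np.linalg.norm(c - g.positions[i]) <= 4.5
            )
            assert g.scores[i] == expected


class TestDesignateHotspots:
    def _scored_grid(self, extent, buried, favor):
        from dataclasses import replace

        g = build_site_grid(np.zeros(3), 1.0, extent)
        scores = np.full(g.n_points, np.nan)
        scores[buried] = favor[buried]
        return replace(
            g, in_site=buried.copy(), buried=buried.copy(), scores=scores
        )

    def test_uniform_block_interior_is_hotspot(self):
        g = build_site_grid(np.zeros(3), 1.0, 1.0)
        buried = np.ones(g.n_points, dtype=bool)
        g = self._scored_grid(1.0, buried, np.ones(g.n_points))
        g = designate_hotspots(g)
        center = np.all(g.lattice == 0, axis=1)
        assert g.candidate.all()
        assert g.hotspot[center][0]  # 26 candidate neighbours

    def test_isolated_candidate_not_hotspot(self):
        g0 = build_site_grid(np.zeros(3), 1.0, 2.0)
        buried = np.all(g0.lattice == 0, axis=1)
        g = self._scored_grid(2.0, buried, np.ones(g0.n_points))
        g = designate_hotspots(g)
        assert g.candidate.sum() == 1
        assert not g.hotspot.any()

    @pytest.mark.parametrize("seed", range(3))
    def test_random_field_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g0 = build_site_grid(np.zeros(3), 1.0, 2.0)
        buried = rng.random(g0.n_points) < 0.5
        favor = rng.random(g0.n_points)
        g = self._scored_grid(2.0, buried, favor)
        g = designate_hotspots(g)
        cand_o, hot_o = hotspot_oracle(g0.lattice, buried, favor)
        np.testing.assert_array_equal(g.candidate, cand_o)
        np.testing.assert_array_equal(g.hotspot, hot_o)

    def test_empty_scored_set_warns_not_raises(self):
        g0 = build_site_grid(np.zeros(3), 1.0, 1.0)
        g = self._scored_grid(1.0, np.zeros(g0.n_points, dtype=bool),
                              np.zeros(g0.n_points))
        with pytest.warns(UserWarning):
            g = designate_hotspots(g)
        assert not g.hotspot.any()

    def test_neighbor_counts_match_oracle(self, rng):
        g = build_site_grid(np.zeros(3), 1.0, 2.0)
        mask = rng.random(g.n_points) < 0.4
        for connectivity in (26, 6):
            np.testing.assert_array_equal(
                g.neighbor_counts(mask, connectivity),
                neighbor_count_oracle(g.lattice, mask, connectivity),
            )


class TestTopHotspots:
    def test_four_distinct_scores_keep_best(self):
        mask = select_top_hotspots([1.0, 3.0, 2.0, 4.0], top_fraction=0.25)
        np.testing.assert_array_equal(mask, [False, False, False, True])

    def test_all_equal_all_retained(self):
        assert select_top_hotspots(np.full(9, 2.5)).all()

    def test_hundred_scores_match_sort_oracle(self, rng):
        scores = rng.normal(size=100)
        mask = select_top_hotspots(scores, top_fraction=0.25)
        thresh = np.quantile(scores, 0.75)
        np.testing.assert_array_equal(mask, scores >= thresh)


class TestMapEnsemble:
    @pytest.fixture
    def cage_setup(self):
        cage, _, _ = make_cage_pocket(CagePocketConfig(seed=3))
        seg = ResidueSelection({"shell": ("A", 1, cage.n_atoms)})
        lig = point_ligand()
        params = HotspotParams(half_extent=4.0, site_cutoff=10.0)
        return cage, seg, lig, params

    def test_identical_conformations_identical_maps(self, cage_setup):
        cage, seg, lig, params = cage_setup
        res = map_ensemble([cage, cage, cage], cage, seg, lig, params=params)
        h0 = res.grids[0].hotspot
        assert h0.any()
        for g in res.grids[1:]:
            np.testing.assert_array_equal(g.hotspot, h0)
        np.testing.assert_array_equal(res.consensus, 3 * h0.astype(int))

    def test_recurrence_filter_two_of_three(self, cage_setup):
        consensus = np.array([0, 1, 2, 3, 2])
        np.testing.assert_array_equal(
            consensus_filter(consensus, min_count=2),
            [False, False, True, True, True],
        )

    def test_rigidly_moved_conformation_same_map(self, cage_setup):
        cage, seg, lig, params = cage_setup
        res = map_ensemble([cage], cage, seg, lig, params=params)
        R = Rotation.random(random_state=21).as_matrix()
        moved = cage.with_coords(cage.coords @ R.T + [6.0, -2.0, 9.0])
        res2 = map_ensemble([moved], cage, seg, lig, params=params)
        np.testing.assert_array_equal(res.consensus, res2.consensus)

    def test_flag_hierarchy(self, cage_setup):
        cage, seg, lig, params = cage_setup
        res = map_ensemble([cage], cage, seg, lig, params=params)
        g = res.grids[0]
        assert not (g.hotspot & ~g.candidate).any()
        assert not (g.candidate & ~g.buried).any()
        assert not (g.buried & ~g.in_site).any()
        assert not (g.in_site & g.pruned).any()

    def test_missing_segment_is_pairing_error(self, cage_setup):
        from pocketdyn.errors import PairingError

        cage, seg, lig, params = cage_setup
        truncated = Structure(
            chain_id=cage.chain_id[:50],
            res_id=cage.res_id[:50],
            ins_code=cage.ins_code[:50],
            res_name=cage.res_name[:50],
            atom_name=cage.atom_name[:50],
            element=cage.element[:50],
            coords=cage.coords[:50],
            hetero=cage.hetero[:50],
        )
        with pytest.raises(PairingError):
            map_ensemble([truncated], cage, seg, lig, params=params)
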