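"""Clustering workflow stages: gates, denoising, assignment, classification."""

import numpy as np
import pytest

from aznano import (
    ClusterParams,
    LocalizationTable,
    ScaffoldCluster,
    assign_to_scaffold,
    classify_synaptic,
    cluster_scaffold,
    denoise_by_reference,
    denoise_single_channel,
    extract_subclusters,
    extract_superclusters,
    parameter_scan,
)
from aznano.cluster_core import area_gate, hdbscan_labels
from aznano.geometry import center_of_mass


def grid_points(width, height, spacing, origin=(0.0, 0.0)):
    """Regular grid filling a width x height rectangle; its alpha-shape area
    at small alpha is exactly width*height."""
    xs = np.arange(0, width + spacing / 2, spacing) + origin[0]
    ys = np.arange(0, height + spacing / 2, spacing) + origin[1]
    return np.array([(x, y) for x in xs for y in ys])


def make_sc(sc_id, com, n_locs=2):
    """Constructed SC with its c.o.m. at a chosen position."""
    com = np.asarray(com, float)
    from aznano import Subcluster

    return Subcluster(
        sc_id=sc_id,
        indices=np.arange(n_locs),
        xy=np.tile(com, (n_locs, 1)),
        com=com,
        n_locs=n_locs,
        area_nm2=0.0,
        density=float("nan"),
        degenerate_area=True,
    )


def make_scaffold(az_id, xy, circ=0.9, excluded=False, reason="none"):
    xy = np.asarray(xy, float).reshape(-1, 2)
    return ScaffoldCluster(
        az_id=az_id,
        indices=np.arange(len(xy)),
        xy=xy,
        com=center_of_mass(xy),
        area_um2=0.1,
        circularity=circ,
        excluded=excluded,
        exclusion_reason=reason,
        n_locs=len(xy),
    )


class TestClusterParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ClusterParams(1, 2)
        with pytest.raises(ValueError):
            ClusterParams(2, 0)
        with pytest.raises(ValueError):
            ClusterParams(2, 2, "centroid")


class TestAreaGate:
    @pytest.mark.parametrize(
        "area,excluded,reason",
        [
            (0.03, True, "too-small"),  # inclusive lower bound
            (0.030001, False, "none"),
            (0.299999, False, "none"),
            (0.3, True, "too-large"),  # inclusive upper bound
            (0.01, True, "too-small"),
            (0.5, True, "too-large"),
        ],
    )
    def test_boundaries(self, area, excluded, reason):
        got_excl, got_reason = area_gate(area)
        assert (got_excl, got_reason) == (excluded, reason)


class TestClusterScaffold:
    def test_recovers_well_separated_azs(self, small_clean_scene):
        cfg, brp, rim, truth = small_clean_scene
        scaffolds = cluster_scaffold(brp)
        assert len(scaffolds) == cfg.n_az
        assert sum(not s.excluded for s in scaffolds) == cfg.n_az
        # each scaffold c.o.m. sits at a true AZ centre
        az_xy = truth.az[["x", "y"]].to_numpy()
        for s in scaffolds:
            assert np.hypot(*(az_xy - s.com).T).min() < 30.0

    def test_small_blob_flagged_too_small(self):
        """A 441-localization blob of area 0.01 um^2 is extracted but
        excluded by the lower area gate.  A second, gate-passing blob is
        present because a density hierarchy needs at least two clusters."""
        small = grid_points(100, 100, spacing=5.0)  # area exactly 0.01 um^2
        big = grid_points(300, 300, spacing=10.0, origin=(5000.0, 5000.0))
        table = LocalizationTable.from_points(np.vstack([small, big]))
        scaffolds = cluster_scaffold(table, ClusterParams(100, 25), alpha=800.0)
        assert len(scaffolds) == 2
        by_area = sorted(scaffolds, key=lambda s: s.area_um2)
        assert by_area[0].area_um2 == pytest.approx(0.01)
        assert by_area[0].excluded and by_area[0].exclusion_reason == "too-small"
        assert not by_area[1].excluded

    def test_empty_input_empty_result(self):
        assert cluster_scaffold(LocalizationTable.from_points(np.empty((0, 2)))) == []

    def test_member_sets_disjoint(self, small_clean_scene):
        cfg, brp, rim, truth = small_clean_scene
        scaffolds = cluster_scaffold(brp)
        all_idx = np.concatenate([s.indices for s in scaffolds])
        assert len(all_idx) == len(set(all_idx))
        assert len(all_idx) <= len(brp)  # clustered + noise = total


class TestDenoiseByReference:
    def test_twenty_nm_rule(self):
        rim = LocalizationTable.from_points([[0, 10], [0, 30]])
        kept = denoise_by_reference(rim, np.array([[0.0, 0.0]]), threshold=20.0)
        np.testing.assert_allclose(kept.xy, [[0, 10]])

    def test_boundary_distance_inclusive(self):
        rim = LocalizationTable.from_points([[0, 20], [0, 20.0001]])
        kept = denoise_by_reference(rim, np.array([[0.0, 0.0]]), threshold=20.0)
        np.testing.assert_allclose(kept.xy, [[0, 20]])

    def test_infinite_threshold_is_identity(self, rng):
        rim = LocalizationTable.from_points(rng.uniform(0, 100, (50, 2)))
        kept = denoise_by_reference(rim, np.array([[0.0, 0.0]]), threshold=np.inf)
        assert len(kept) == 50

    def test_empty_reference_raises(self):
        rim = LocalizationTable.from_points([[0, 0]])
        with pytest.raises(ValueError):
            denoise_by_reference(rim, np.empty((0, 2)))

    def test_matches_exhaustive_all_pairs_filter(self, rng):
        rim_xy = rng.uniform(0, 2000, (500, 2))
        brp_xy = rng.uniform(0, 2000, (500, 2))
        kept = denoise_by_reference(LocalizationTable.from_points(rim_xy), brp_xy, 20.0)
        d = np.sqrt(((rim_xy[:, None] - brp_xy[None]) ** 2).sum(-1)).min(axis=1)
        np.testing.assert_allclose(kept.xy, rim_xy[d <= 20.0])


class TestDenoiseSingleChannel:
    def test_background_discarded_preferentially_to_signal(self, default_scene):
        """With dense SC structure present, the first pass keeps signal and
        treats most of the uniform background as noise."""
        cfg, brp, rim, truth = default_scene
        from aznano.cluster_core import hdbscan_labels

        labels = hdbscan_labels(rim.xy, ClusterParams(20, 5))
        kept = labels >= 0
        is_bg = rim.data["sc_id"].to_numpy() == -1
        assert kept[~is_bg].mean() > 0.9
        assert kept[is_bg].mean() < 0.5

    def test_clean_scene_high_retention(self, clean_scene):
        cfg, brp, rim, truth = clean_scene
        kept = denoise_single_channel(rim)
        assert len(kept) >= 0.85 * len(rim)

    def test_idempotent_within_one_percent(self, clean_scene):
        cfg, brp, rim, truth = clean_scene
        once = denoise_single_channel(rim)
        twice = denoise_single_channel(once)
        assert len(twice) >= 0.99 * len(once)


class TestExtractSubclusters:
    def test_two_minimal_pairs(self):
        pts = np.array([[0, 0], [5, 0], [200, 0], [205, 0]], float)
        scs = extract_subclusters(LocalizationTable.from_points(pts))
        assert len(scs) == 2
        assert sorted(sc.n_locs for sc in scs) == [2, 2]

    def test_two_point_sc_has_degenerate_area(self):
        pts = np.array([[0, 0], [5, 0], [200, 0], [205, 0]], float)
        scs = extract_subclusters(LocalizationTable.from_points(pts))
        assert all(sc.degenerate_area and sc.area_nm2 == 0.0 for sc in scs)
        assert all(np.isnan(sc.density) for sc in scs)

    def test_fewer_than_two_points_empty(self):
        assert extract_subclusters(LocalizationTable.from_points([[0.0, 0.0]])) == []

    def test_partition_property(self, clean_scene):
        cfg, brp, rim, truth = clean_scene
        scs = extract_subclusters(denoise_single_channel(rim))
        all_idx = np.concatenate([sc.indices for sc in scs])
        assert len(all_idx) == len(set(all_idx))  # each localization at most once

    def test_every_recovered_sc_maps_to_one_generative_sc(self, clean_scene):
        """Fragmentation may split a generative SC, but recovered clusters
        should not straddle two generative SCs (they are ~74 nm apart)."""
        cfg, brp, rim, truth = clean_scene
        denoised = denoise_single_channel(rim)
        scs = extract_subclusters(denoised)
        src = denoised.data["sc_id"].to_numpy()
        pure = sum(1 for sc in scs if len(set(src[sc.indices])) == 1)
        # SC directions are uniform, so occasional angle collisions put two
        # generative SCs within a blink-cloud width of each other
        assert pure / len(scs) > 0.85


class TestAssignAndClassify:
    def test_nearest_scaffold_wins(self):
        s1 = make_scaffold(0, [[80.0, 0.0]])
        s2 = make_scaffold(1, [[300.0, 0.0]])
        scs = [make_sc(0, [0.0, 0.0])]
        assign_to_scaffold(scs, [s1, s2])
        assert scs[0].az_id == 0
        assert scs[0].dist_to_scaffold_nm == pytest.approx(80.0)

    def test_radial_distance_is_com_to_com(self):
        scaffold = make_scaffold(0, [[0.0, 0.0]])
        scs = [make_sc(0, [120.0, 0.0])]
        assign_to_scaffold(scs, [scaffold])
        assert scs[0].radial_distance_nm == pytest.approx(120.0)

    def test_no_scaffolds_raises(self):
        with pytest.raises(ValueError):
            assign_to_scaffold([make_sc(0, [0.0, 0.0])], [])

    def test_assignment_matches_truth_parentage(self, clean_scene):
        """AZs are separated by >> 400 nm, so every SC fragment must be
        assigned to its generative parent AZ."""
        cfg, brp, rim, truth = clean_scene
        scaffolds = cluster_scaffold(brp)
        denoised = denoise_single_channel(rim)
        scs = assign_to_scaffold(extract_subclusters(denoised), scaffolds)
        src = denoised.data["sc_id"].to_numpy()
        sc_parent = truth.sc.set_index("sc_id").az_id
        az_xy = truth.az.set_index("az_id")[["x", "y"]]
        hits = 0
        for sc in scs:
            true_az = sc_parent.loc[src[sc.indices[0]]]
            assigned_com = next(s.com for s in scaffolds if s.az_id == sc.az_id)
            d = np.hypot(*(az_xy.loc[true_az].to_numpy() - assigned_com))
            hits += d < cfg.az_ring_radius
        assert hits == len(scs)

    @pytest.mark.parametrize(
        "dist,circ,expected",
        [
            (50.0, 0.9, "intrasynaptic"),  # inclusive at 50
            (50.1, 0.9, "vicinity"),
            (200.0, 0.7, "vicinity"),
            (200.0, 0.5, "extrasynaptic-far"),  # circularity gate fails
            (400.0, 0.9, "vicinity"),  # inclusive at 400
            (400.5, 0.9, "extrasynaptic-far"),
            (200.0, 0.6, "vicinity"),  # gate itself inclusive
        ],
    )
    def test_synaptic_class_boundaries(self, dist, circ, expected):
        scaffold = make_scaffold(0, [[0.0, 0.0]], circ=circ)
        scs = [make_sc(0, [dist, 0.0])]
        assign_to_scaffold(scs, [scaffold])
        classify_synaptic(scs, [scaffold])
        assert scs[0].synaptic_class == expected

    def test_excluded_scaffold_propagates(self):
        scaffold = make_scaffold(0, [[0.0, 0.0]], excluded=True, reason="too-small")
        scs = [make_sc(0, [10.0, 0.0])]
        assign_to_scaffold(scs, [scaffold])
        assert scs[0].excluded


class TestSuperclusters:
    def _six_coms(self):
        coms = [[0, 0], [10, 5], [5, 10], [150, 0], [160, 5], [155, 10]]
        return [make_sc(i, c) for i, c in enumerate(coms)]

    def test_two_tight_groups(self):
        scs = self._six_coms()
        spcs = extract_superclusters(scs)
        assert len(spcs) == 2
        assert all(len(spc.member_sc_ids) == 3 for spc in spcs)
        assert all(sc.spc_id >= 0 for sc in scs)  # 100% clustered

    def test_single_sc_no_spc(self):
        assert extract_superclusters([make_sc(0, [0.0, 0.0])]) == []

    def test_mixed_azs_rejected(self):
        scs = self._six_coms()
        scs[0].az_id = 0
        scs[1].az_id = 1
        with pytest.raises(ValueError):
            extract_superclusters(scs)

    def test_spc_com_is_com_of_member_coms(self):
        scs = self._six_coms()
        for spc in extract_superclusters(scs):
            members = [sc for sc in scs if sc.sc_id in spc.member_sc_ids]
            np.testing.assert_allclose(spc.com, np.mean([m.com for m in members], axis=0))
            d = [np.hypot(*(m.com - spc.com)) for m in members]
            assert spc.mean_sc_distance_nm == pytest.approx(np.mean(d))


class TestParameterScan:
    def test_single_image_median_is_count(self, small_clean_scene):
        cfg, brp, rim, truth = small_clean_scene
        table = parameter_scan([rim], [(5, 20)])
        labels = hdbscan_labels(rim.xy, ClusterParams(20, 5))
        assert table.iloc[0].median_cluster_count == labels.max() + 1

    def test_count_monotone_in_min_cluster_size(self, small_clean_scene):
        cfg, brp, rim, truth = small_clean_scene
        grid = [(5, 10), (5, 20), (5, 40)]
        table = parameter_scan([rim], grid)
        counts = table.sort_values("min_cluster_size").median_cluster_count.to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_empty_image_list_raises(self):
        with pytest.raises(ValueError):
            parameter_scan([], [(5, 20)])

    def test_empty_grid_empty_table(self, small_clean_scene):
        cfg, brp, rim, truth = small_clean_scene
        assert len(parameter_scan([rim], [])) == 0
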