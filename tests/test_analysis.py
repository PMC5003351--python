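"""Cluster statistics, growth-rate fitting, cross-sections, height profiles."""

import numpy as np
import pytest

import microwell_mc as mw
from microwell_mc.analysis import CELL, VACANT, WALL

from conftest import make_snapshot


def networkx_cluster_sizes(coords):
    """Independent BFS oracle for face-connected components."""
    import networkx as nx

    g = nx.Graph()
    pts = {tuple(c) for c in coords}
    g.add_nodes_from(pts)
    for x, y, z in pts:
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (x + d[0], y + d[1], z + d[2])
            if nb in pts:
                g.add_edge((x, y, z), nb)
    return sorted((len(c) for c in nx.connected_components(g)), reverse=True)


class TestLabelClusters:
    def test_single_cell(self):
        snap = make_snapshot([(3, 4, 5)], (10, 10, 10))
        stats = mw.label_clusters(snap)
        assert stats.n_clusters == 1
        assert list(stats.sizes) == [1]
        assert stats.largest_fraction == 1.0

    def test_diagonal_cells_are_separate(self):
        snap = make_snapshot([(10, 10, 40), (11, 11, 40)], (20, 20, 50))
        assert mw.label_clusters(snap).n_clusters == 2

    def test_2x2x2_block_single_cluster(self):
        coords = [(x, y, z) for x in (4, 5) for y in (4, 5) for z in (4, 5)]
        snap = make_snapshot(coords, (10, 10, 10))
        stats = mw.label_clusters(snap)
        assert stats.n_clusters == 1
        assert list(stats.sizes) == [8]
        assert stats.centroids[0] == pytest.approx([4.5, 4.5, 4.5])

    def test_sizes_match_independent_bfs_on_random_config(self):
        rng = np.random.default_rng(0)
        coords = np.unique(rng.integers(0, 12, size=(300, 3)), axis=0)
        snap = make_snapshot(coords, (12, 12, 12))
        stats = mw.label_clusters(snap)
        assert list(stats.sizes) == networkx_cluster_sizes(coords)
        assert int(stats.sizes.sum()) == snap.n_cells

    def test_periodic_wrapping_joins_boundary_clusters(self):
        dom = mw.build_periodic_domain(6)
        snap = make_snapshot([(0, 2, 2), (5, 2, 2)], (6, 6, 6), N=dom.N)
        stats = mw.label_clusters(snap, domain=dom)
        assert stats.n_clusters == 1

    def test_empty_snapshot(self):
        snap = make_snapshot(np.zeros((0, 3)), (5, 5, 5))
        stats = mw.label_clusters(snap)
        assert stats.n_clusters == 0
        assert stats.largest_fraction == 0.0

    def test_aggregate_filter(self):
        snap = make_snapshot([(1, 1, 1), (1, 1, 2), (4, 4, 4)], (8, 8, 8))
        stats = mw.label_clusters(snap)
        assert stats.n_clusters == 2
        assert stats.n_aggregates(min_size=2) == 1


class TestFitGrowthRate:
    def test_recovers_exact_exponential(self):
        t = np.linspace(0, 500, 100)
        n = np.round(5 * np.exp(0.01 * t)).astype(np.int64)
        trace = mw.KineticsTrace(time=t, n_cells=n, N=100000)
        rate = mw.fit_growth_rate(trace, window=(0.0, 1.0))
        assert rate == pytest.approx(0.01, rel=0.02)

    def test_constant_trace_raises(self):
        trace = mw.KineticsTrace(
            time=np.linspace(0, 10, 50),
            n_cells=np.full(50, 7, dtype=np.int64),
            N=1000,
        )
        with pytest.raises(mw.GrowthFitError):
            mw.fit_growth_rate(trace, window=(0.0, 1.0))

    def test_too_few_points_raises(self):
        trace = mw.KineticsTrace(
            time=np.arange(5.0), n_cells=np.arange(1, 6), N=1000
        )
        with pytest.raises(mw.GrowthFitError):
            mw.fit_growth_rate(trace, window=(0.0, 1.0))


class TestCrossSection:
    def test_empty_snapshot_has_no_cell_pixels(self, half_well):
        snap = make_snapshot(np.zeros((0, 3)), half_well.dims, N=half_well.N)
        grid = mw.cross_section(snap, half_well)
        assert set(np.unique(grid)) <= {WALL, VACANT}
        # the well interior appears in the section
        assert (grid == VACANT).sum() > 0

    def test_cell_on_the_plane_appears_once(self, half_well):
        snap = make_snapshot([(15, 15, 20)], half_well.dims, N=half_well.N)
        grid = mw.cross_section(snap, half_well)
        assert (grid == CELL).sum() == 1

    def test_cell_off_the_plane_is_invisible(self, half_well):
        snap = make_snapshot([(15, 3, 20)], half_well.dims, N=half_well.N)
        grid = mw.cross_section(snap, half_well)
        assert (grid == CELL).sum() == 0

    def test_mid_plane_union_covers_both_parity_slices(self, half_well):
        snap = make_snapshot([(15, 14, 20), (10, 15, 20)], half_well.dims,
                             N=half_well.N)
        grid = mw.cross_section(snap, half_well)
        assert (grid == CELL).sum() == 2

    def test_out_of_range_plane_rejected(self, half_well):
        snap = make_snapshot([(15, 15, 20)], half_well.dims, N=half_well.N)
        with pytest.raises(ValueError):
            mw.cross_section(snap, half_well, plane=("y", 99))
        with pytest.raises(ValueError):
            mw.cross_section(snap, half_well, plane=("w", 0))


class TestHeightProfile:
    def test_all_cells_in_one_layer(self):
        snap = make_snapshot([(1, 2, 3), (4, 5, 3), (2, 2, 3)], (8, 8, 8))
        prof = mw.height_profile(snap)
        assert prof.mean_height == 3.0
        assert prof.counts[3] == 3
        assert prof.counts.sum() == 3

    def test_uniform_cylinder_occupancy_mean_is_midpoint(self, half_well):
        # every cylinder-section site occupied: mean z = midpoint of layers
        zs = half_well.z_split
        sites = half_well.sites
        cyl = sites[sites[:, 2] >= zs]
        snap = make_snapshot(cyl, half_well.dims, N=half_well.N)
        prof = mw.height_profile(snap, half_well)
        expected = (zs + (half_well.dims[2] - 1)) / 2
        assert prof.mean_height == pytest.approx(expected, abs=1e-9)

    def test_empty_profile(self):
        snap = make_snapshot(np.zeros((0, 3)), (5, 5, 7))
        prof = mw.height_profile(snap)
        assert prof.counts.sum() == 0
        assert np.isnan(prof.mean_height)


class TestWallContactFraction:
    def test_counts_only_adhesive_contacts(self, tiny_box):
        # (0,0,0) has 3 contacts; (3,3,5) touches only the exempt top plane;
        # (3,3,3) is interior.
        snap = make_snapshot([(0, 0, 0), (3, 3, 5), (3, 3, 3)],
                             tiny_box.dims, N=tiny_box.N)
        frac = mw.wall_contact_fraction(snap, tiny_box)
        assert frac == pytest.approx(1 / 3)
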