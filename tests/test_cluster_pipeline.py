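import numpy as np
import pandas as pd
import pytest

from qsmcl import (ClusterParams, KineticsConfig, LocalizationTable,
                   MoleculeSet, dbscan_clusters, default_min_pts,
                   detection_efficiency, filter_clusters, gen_origami_grid,
                   gen_site_pairs, mean_frame_filter, nena_precision,
                   resolve_pairs_benchmark, simulate_imaging,
                   smallest_resolved_separation, std_frame_filter)
from qsmcl.cluster_pipeline import ClusterRecord, greedy_match, optimal_match


def make_table(xy, frames=None, n_frames=1000):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.zeros(len(xy), dtype=int)
    return LocalizationTable(
        pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "frame": frames}),
        n_frames=n_frames)


def brute_force_dbscan(xy, eps, min_pts):
    """Independent neighborhood-graph DBSCAN: core partition + noise set."""
    n = len(xy)
    d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = {i for i in range(n) if len(neighbors[i]) >= min_pts}
    # connected components of core points through eps-reachability
    comp = {}
    for i in sorted(core):
        if i in comp:
            continue
        stack, cid = [i], len(set(comp.values()))
        while stack:
            j = stack.pop()
            if j in comp:
                continue
            comp[j] = cid
            stack.extend(k for k in neighbors[j] if k in core and k not in comp)
    border = {}
    for i in range(n):
        if i in core:
            continue
        reach = [comp[j] for j in sorted(neighbors[i]) if j in core]
        if reach:
            border[i] = set(reach)     # any reachable core cluster is valid
    noise = set(range(n)) - core - set(border)
    return comp, border, noise


class TestNeNA:
    def test_recovers_simulated_precision(self, sparse_sites_table):
        """NeNA on 7 nm noise data returns ~7 nm (within 10%)."""
        _, table, _ = sparse_sites_table
        assert nena_precision(table) == pytest.approx(7.0, rel=0.10)

    @pytest.mark.parametrize("sigma", [2.0, 4.0])
    def test_scale_equivariance(self, nnd_kinetics, sigma):
        layout = gen_origami_grid(4, 4, spacing_nm=2_000.0)
        cfg = KineticsConfig(n_frames=20_000, sigma_nm=sigma)
        table, _ = simulate_imaging(layout, cfg, seed=31)
        assert nena_precision(table) == pytest.approx(sigma, rel=0.10)

    def test_too_few_pairs_raises(self):
        table = make_table([[0, 0], [1, 1]], frames=[0, 5])
        with pytest.raises(ValueError):
            nena_precision(table)


class TestDBSCAN:
    @pytest.mark.parametrize("seed,n,eps,min_pts", [
        (0, 120, 30.0, 4), (1, 300, 20.0, 6), (2, 500, 40.0, 10), (3, 60, 60.0, 3),
    ])
    def test_matches_brute_force_oracle(self, seed, n, eps, min_pts):
        """DBSCAN partition equals an exhaustive neighborhood-graph run."""
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 800, size=(n, 2))
        table = make_table(xy, frames=rng.integers(0, 100, n))
        records = dbscan_clusters(table, ClusterParams(eps, min_pts, 1000))
        comp, border, noise = brute_force_dbscan(xy, eps, min_pts)
        assigned = {}
        for rec in records:
            for m in rec.members:
                assigned[int(m)] = rec.id
        # identical noise set
        assert set(range(n)) - set(assigned) == noise
        # identical partition of core points
        ours = {}
        for i, cid in comp.items():
            ours.setdefault(cid, set()).add(assigned[i])
        oracle_parts = {frozenset(k for k, v in comp.items() if v == cid)
                        for cid in set(comp.values())}
        our_parts = {frozenset(i for i in comp if assigned[i] == c)
                     for c in {assigned[i] for i in comp}}
        assert oracle_parts == our_parts
        # border points sit in a cluster containing a reachable core point
        core_cluster = {i: assigned[i] for i in comp}
        for i, valid in border.items():
            valid_ids = {assigned[j] for j in comp if comp[j] in valid}
            assert assigned[i] in valid_ids

    def test_empty_table_gives_empty_list(self):
        empty = make_table(np.empty((0, 2)))
        assert dbscan_clusters(empty, ClusterParams(10.0, 5, 100)) == []

    def test_sparse_noise_yields_no_clusters(self, rng):
        xy = rng.uniform(0, 10_000, size=(400, 2))
        table = make_table(xy)
        assert dbscan_clusters(table, ClusterParams(10.0, 10, 100)) == []

    def test_record_statistics_match_recomputation(self, rng):
        xy = rng.normal(0, 5, size=(50, 2))
        frames = rng.integers(0, 1000, 50)
        table = make_table(xy, frames)
        (rec,) = dbscan_clusters(table, ClusterParams(30.0, 5, 1000))
        np.testing.assert_allclose(rec.centroid, xy.mean(0))
        assert rec.mean_frame == pytest.approx(frames.mean())
        assert rec.std_frame == pytest.approx(frames.std())
        assert rec.n_locs == 50

    def test_order_independence(self, rng):
        xy = rng.uniform(0, 300, size=(200, 2))
        frames = rng.integers(0, 100, 200)
        table = make_table(xy, frames)
        perm = rng.permutation(200)
        shuffled = make_table(xy[perm], frames[perm])
        a = dbscan_clusters(table, ClusterParams(25.0, 5, 100))
        b = dbscan_clusters(shuffled, ClusterParams(25.0, 5, 100))
        cents_a = sorted(map(tuple, np.round([r.centroid for r in a], 9)))
        cents_b = sorted(map(tuple, np.round([r.centroid for r in b], 9)))
        assert cents_a == cents_b


def cluster_with_frames(cid, frames, n_frames):
    frames = np.asarray(frames, dtype=float)
    return ClusterRecord(id=cid, members=np.arange(len(frames)),
                         centroid=np.zeros(2), n_locs=len(frames),
                         mean_frame=float(frames.mean()),
                         std_frame=float(frames.std()), area_nm2=0.0)


class TestTemporalFilters:
    def test_uniform_clusters_retained(self, rng):
        """Clouds visited uniformly over the acquisition all survive."""
        n_frames = 10_000
        clusters = [cluster_with_frames(i, rng.uniform(0, n_frames, 200), n_frames)
                    for i in range(30)]
        assert len(mean_frame_filter(clusters, n_frames)) == 30

    def test_early_cluster_removed(self, rng):
        n_frames = 10_000
        good = [cluster_with_frames(i, rng.uniform(0, n_frames, 200), n_frames)
                for i in range(20)]
        early = cluster_with_frames(99, rng.uniform(0, 0.05 * n_frames, 200), n_frames)
        kept = mean_frame_filter(good + [early], n_frames)
        assert early not in kept
        assert len(kept) == 20

    def test_identical_temporal_structure_all_retained(self):
        clusters = [cluster_with_frames(i, [100, 200, 300], 1000) for i in range(5)]
        assert len(mean_frame_filter(clusters, 1000)) == 5

    def test_single_cluster_passes_through_with_warning(self):
        c = [cluster_with_frames(0, [1, 2], 100)]
        with pytest.warns(UserWarning):
            assert mean_frame_filter(c, 100) == c

    def test_sticking_event_removed_by_std_filter(self, rng):
        """A 200-frame sticking block (SD ~ 58 frames) falls below cutoff."""
        n_frames = 10_000
        stick = cluster_with_frames(0, np.arange(5_000, 5_200), n_frames)
        assert stick.std_frame == pytest.approx(200 / np.sqrt(12), rel=0.02)
        uniform = cluster_with_frames(1, rng.uniform(0, n_frames, 300), n_frames)
        kept = std_frame_filter([stick, uniform], n_frames)
        assert kept == [uniform]

    def test_std_filter_empty_input(self):
        assert std_frame_filter([], 1000) == []

    def test_filters_are_idempotent(self, rng):
        n_frames = 10_000
        clusters = [cluster_with_frames(i, rng.uniform(0, n_frames, 150), n_frames)
                    for i in range(25)]
        clusters.append(cluster_with_frames(90, np.arange(100, 260), n_frames))
        clusters.append(cluster_with_frames(91, rng.uniform(0, 400, 100), n_frames))
        once_mean = mean_frame_filter(clusters, n_frames)
        assert mean_frame_filter(once_mean, n_frames) == once_mean
        once_std = std_frame_filter(clusters, n_frames)
        assert std_frame_filter(once_std, n_frames) == once_std


class TestDetectionEfficiency:
    def test_perfect_recovery(self):
        truth = MoleculeSet("A", [[0, 0], [100, 0], [0, 100]])
        clusters = [ClusterRecord(i, np.array([i]), p, 1, 0, 0, 0.0)
                    for i, p in enumerate(truth.points)]
        assert detection_efficiency(clusters, truth, 20.0) == 1.0

    def test_half_recovery(self):
        truth = MoleculeSet("A", [[0, 0], [100, 0], [0, 100], [100, 100]])
        clusters = [ClusterRecord(i, np.array([i]), p, 1, 0, 0, 0.0)
                    for i, p in enumerate(truth.points[:2])]
        assert detection_efficiency(clusters, truth, 20.0) == 0.5

    def test_empty_truth_raises(self):
        truth = MoleculeSet("A", np.empty((0, 2)))
        with pytest.raises(ValueError):
            detection_efficiency([], truth)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matching_equals_optimal_cardinality(self, seed):
        """One-to-one matching recovers the exhaustive optimal assignment size."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 200, size=(rng.integers(5, 20), 2))
        b = rng.uniform(0, 200, size=(rng.integers(5, 20), 2))
        radius = 60.0
        got = len(optimal_match(a, b, radius))
        g = nx.Graph()
        g.add_nodes_from((f"a{i}" for i in range(len(a))), bipartite=0)
        for i, p in enumerate(a):
            for j, q in enumerate(b):
                if np.hypot(*(p - q)) <= radius:
                    g.add_edge(f"a{i}", f"b{j}")
        best = len(nx.max_weight_matching(g, maxcardinality=True))
        assert got == best


class TestResolutionBenchmark:
    def test_pairs_resolved_at_30nm(self, nnd_kinetics):
        """Site pairs 30 nm apart resolve into two clouds nearly always."""
        res = resolve_pairs_benchmark([30.0], n_pairs=12, cfg=nnd_kinetics, seed=33)
        assert res[30.0] >= 0.9

    def test_pairs_merge_at_15nm(self, nnd_kinetics):
        res = resolve_pairs_benchmark([15.0], n_pairs=12, cfg=nnd_kinetics, seed=34)
        assert res[15.0] <= 0.2

    def test_smallest_resolved_helper(self):
        res = {20.0: 0.3, 25.0: 0.95, 30.0: 1.0}
        assert smallest_resolved_separation(res) == 25.0
        assert smallest_resolved_separation({20.0: 0.1}) is None


def test_default_min_pts_tracks_binding_frequency():
    cfg = KineticsConfig(influx_rate=0.02, mean_bright_s=0.5, n_frames=80_000)
    # 0.02/s x 8000 s x 5 frames/event = 800 locs -> 0.3 x 800 = 240
    assert default_min_pts(cfg) == 240
    sparse = KineticsConfig(influx_rate=0.001, mean_bright_s=0.1, n_frames=1_000)
    assert default_min_pts(sparse) == 10  # floor
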