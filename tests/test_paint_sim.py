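import numpy as np
import pytest

from qsmcl import (KineticsConfig, RegionMask, apply_labeling,
                   gen_complex_population, gen_origami_grid, gen_random_field,
                   gen_site_pairs, gen_striped_field, nnd,
                   render_localizations, simulate_imaging, simulate_kinetics)
from qsmcl.paint_sim import in_stripe


class TestRandomField:
    def test_zero_density_is_empty(self, roi_10um):
        assert len(gen_random_field(0.0, roi_10um, seed=1)) == 0

    def test_negative_density_rejected(self, roi_10um):
        with pytest.raises(ValueError):
            gen_random_field(-1.0, roi_10um, seed=1)

    def test_poisson_count_statistics(self, roi_5um, rng):
        """Replicate counts match Poisson(density x area) within 3 SE."""
        density, reps = 600.0, 60
        lam = density * roi_5um.area_um2  # 15,000
        counts = [len(gen_random_field(density, roi_5um, rng)) for _ in range(reps)]
        se = np.sqrt(lam / reps)
        assert abs(np.mean(counts) - lam) < 3 * se
        assert np.all([roi_5um.contains(gen_random_field(5, roi_5um, rng).points).all()
                       for _ in range(3)])

    def test_mean_nnd_matches_closed_form(self, roi_5um):
        """Mean NND of a homogeneous field is 0.5/sqrt(rho) (20.41 nm at 600)."""
        field = gen_random_field(600.0, roi_5um, seed=7)
        res = nnd(np.mod(field.points, 5_000.0), boxsize=5_000.0)
        assert res.mean == pytest.approx(20.41, rel=0.02)

    def test_seed_reproducibility(self, roi_5um):
        a = gen_random_field(100.0, roi_5um, seed=42).points
        b = gen_random_field(100.0, roi_5um, seed=42).points
        np.testing.assert_array_equal(a, b)


class TestComplexPopulation:
    def test_zero_fraction_leaves_no_partners(self, roi_5um):
        a, b = gen_complex_population(300, 300, 0.0, roi_5um, seed=3)
        assert (a.partner_index == -1).all()
        assert (b.partner_index == -1).all()

    def test_full_fraction_pairs_every_b(self, roi_5um):
        a, b = gen_complex_population(300, 200, 1.0, roi_5um, seed=4)
        paired = b.partner_index >= 0
        assert paired.all()
        d = np.linalg.norm(b.points - a.points[b.partner_index], axis=1)
        assert (d <= 16.0 + 1e-9).all()

    def test_partner_distances_within_range(self, roi_5um):
        a, b = gen_complex_population(400, 400, 0.5, roi_5um, seed=5)
        paired = b.partner_index >= 0
        assert abs(paired.mean() - 0.5) < 0.02
        d = np.linalg.norm(b.points[paired] - a.points[b.partner_index[paired]], axis=1)
        assert d.min() >= 12.0 - 1e-9
        assert d.max() <= 16.0 + 1e-9

    def test_invalid_fraction_rejected(self, roi_5um):
        with pytest.raises(ValueError):
            gen_complex_population(100, 100, 1.5, roi_5um, seed=1)


class TestLabeling:
    def test_extremes(self, roi_5um):
        field = gen_random_field(100.0, roi_5um, seed=6)
        assert apply_labeling(field, 1.0, seed=1).labeled.all()
        assert not apply_labeling(field, 0.0, seed=1).labeled.any()

    def test_binomial_retention_rate(self, roi_5um, rng):
        """LE=0.30 thinning retains 30% of molecules within binomial 3 SE."""
        field = gen_random_field(400.0, roi_5um, seed=8)
        n, reps, le = len(field), 40, 0.30
        kept = [apply_labeling(field, le, rng).labeled.sum() for _ in range(reps)]
        se = np.sqrt(le * (1 - le) / (n * reps))
        assert abs(np.mean(kept) / n - le) < 3 * se


class TestOrigamiLayouts:
    def test_grid_geometry(self):
        grid = gen_origami_grid(3, 4, spacing_nm=20.0)
        assert len(grid) == 12
        d = nnd(grid.coords).distances
        assert d.min() == pytest.approx(20.0)

    def test_single_site_at_origin(self):
        grid = gen_origami_grid(1, 1)
        np.testing.assert_array_equal(grid.coords, [[0.0, 0.0]])

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            gen_origami_grid(2, 2, spacing_nm=0.0)

    def test_site_pairs_separation(self):
        pairs = gen_site_pairs(9, 25.0)
        d = np.linalg.norm(pairs.coords[0::2] - pairs.coords[1::2], axis=1)
        np.testing.assert_allclose(d, 25.0)


class TestStripedField:
    def test_empty_gaps(self, roi_10um):
        field = gen_striped_field(300.0, 0.0, roi_10um, seed=9)
        assert in_stripe(field.points).all()

    def test_equal_densities_match_random_field(self, roi_10um, rng):
        field = gen_striped_field(200.0, 200.0, roi_10um, rng)
        expect = 200.0 * roi_10um.area_um2
        assert abs(len(field) - expect) < 4 * np.sqrt(expect)

    def test_stripe_nnd_below_gap_nnd(self, roi_10um):
        """Dense stripes have shorter NNDs than sparse gaps."""
        field = gen_striped_field(600.0, 30.0, roi_10um, seed=10)
        mask = in_stripe(field.points)
        nnd_stripe = nnd(field.points[mask]).mean
        nnd_gap = nnd(field.points[~mask]).mean
        assert nnd_stripe < nnd_gap


class TestKinetics:
    def test_zero_influx_gives_empty_traces(self):
        layout = gen_origami_grid(2, 2, spacing_nm=100.0)
        cfg = KineticsConfig(influx_rate=0.0, n_frames=1000)
        assert all(t.n_events == 0 for t in simulate_kinetics(layout, cfg, seed=1))

    def test_event_count_matches_renewal_rate(self):
        """Events per site ~ influx x acquisition time (bright << dark)."""
        layout = gen_origami_grid(10, 10, spacing_nm=500.0)
        cfg = KineticsConfig(influx_rate=0.02, mean_bright_s=0.5, n_frames=80_000)
        traces = simulate_kinetics(layout, cfg, seed=11)
        counts = np.array([t.n_events for t in traces])
        # renewal rate = 1/(mean dark + mean bright)
        expect = cfg.total_time_s / (1 / cfg.influx_rate + cfg.mean_bright_s)
        se = np.sqrt(expect / len(counts))
        assert abs(counts.mean() - expect) < 3 * se

    def test_triple_sequence_shortens_dark_time_threefold(self):
        """3x concatenated sequences superpose to a third of the dark time."""
        cfg = KineticsConfig(n_frames=160_000)
        dark = {}
        for spp in (1, 3):
            layout = gen_origami_grid(6, 10, spacing_nm=500.0, sites_per_position=spp)
            traces = simulate_kinetics(layout, cfg, seed=12)
            dark[spp] = np.concatenate([t.dark_intervals_frames() for t in traces]).mean()
        assert dark[3] / dark[1] == pytest.approx(1 / 3, rel=0.1)

    def test_events_within_acquisition_and_sorted(self):
        layout = gen_origami_grid(3, 3, spacing_nm=500.0)
        cfg = KineticsConfig(n_frames=5_000)
        for t in simulate_kinetics(layout, cfg, seed=13):
            ev = np.asarray(t.events)
            if len(ev) == 0:
                continue
            assert ev[:, 0].min() >= 0
            assert (ev[:, 0] + ev[:, 1]).max() <= cfg.n_frames
            gaps = t.dark_intervals_frames()
            assert (gaps > 0).all()  # merged events leave no zero gaps


class TestRendering:
    def test_zero_noise_pins_localizations_to_sites(self):
        layout = gen_origami_grid(2, 2, spacing_nm=200.0)
        cfg = KineticsConfig(n_frames=10_000, sigma_nm=0.0)
        table, traces = simulate_imaging(layout, cfg, seed=14)
        for t in traces:
            locs = table.data[table.data.site_id == t.site_id][["x", "y"]].to_numpy()
            if len(locs):
                np.testing.assert_allclose(
                    locs, np.tile(layout.coords[t.site_id], (len(locs), 1)))

    def test_localization_count_conserves_occupied_frames(self):
        layout = gen_origami_grid(3, 3, spacing_nm=300.0)
        cfg = KineticsConfig(n_frames=20_000)
        traces = simulate_kinetics(layout, cfg, seed=15)
        table = render_localizations(traces, layout, cfg, seed=16)
        assert len(table) == sum(len(t.occupied_frames()) for t in traces)

    def test_noise_sd_recovers_sigma(self):
        """Empirical scatter around the site equals sigma within 5%."""
        layout = gen_origami_grid(1, 1)
        cfg = KineticsConfig(influx_rate=0.2, n_frames=40_000, sigma_nm=7.0)
        table, _ = simulate_imaging(layout, cfg, seed=17)
        assert len(table) >= 1_000
        xy = table.xy
        sd = np.sqrt(((xy - xy.mean(0)) ** 2).sum(1).mean() / 2)
        assert sd == pytest.approx(7.0, rel=0.05)

    def test_bit_identical_for_same_seed(self):
        layout = gen_origami_grid(2, 2, spacing_nm=100.0)
        cfg = KineticsConfig(n_frames=5_000)
        t1, _ = simulate_imaging(layout, cfg, seed=18)
        t2, _ = simulate_imaging(layout, cfg, seed=18)
        assert t1.data.equals(t2.data)
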