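import numpy as np
import pytest

from spotcoloc.coloc import (
    ColocError,
    RoiPolygon,
    aggregate_cells,
    filter_roi,
    match_directed,
    multi_colocalised,
    net_colocalisation,
    percent_colocalised,
    scramble_map,
)
from spotcoloc.config import AcquisitionConfig
from spotcoloc.detect import ParticleMap


def make_map(xy, channel="a", field_shape=(256, 256), pixel_size_nm=107.5):
    xy = np.asarray(xy, float).reshape(-1, 2)
    return ParticleMap(
        xy=xy,
        brightness=np.ones(len(xy)),
        channel=channel,
        field_shape=field_shape,
        pixel_size_nm=pixel_size_nm,
    )


def brute_force_flags(source, target, threshold_nm):
    """Exhaustive O(n^2) oracle for the nearest-neighbour matching."""
    flags, dists = [], []
    for p in source.xy_nm:
        d = np.sqrt(((target.xy_nm - p) ** 2).sum(axis=1))
        dists.append(d.min() if len(d) else np.inf)
        flags.append(len(d) > 0 and d.min() < threshold_nm)
    return np.array(flags), np.array(dists)


class TestMatchDirected:
    def test_identity_maps_fully_colocalised(self, random_map_factory, cfg60):
        m = random_map_factory(30, seed=1)
        match = match_directed(m, m, cfg60.threshold_nm)
        assert percent_colocalised(match) == 100.0
        assert np.all(match.nearest_nm == 0.0)

    def test_exact_threshold_distance_not_colocalised(self, cfg60):
        # two particles exactly 2 px = 215 nm apart: strict inequality
        src = make_map([(10.0, 10.0)])
        tgt = make_map([(12.0, 10.0)], channel="b")
        match = match_directed(src, tgt, cfg60.threshold_nm)
        assert match.nearest_nm[0] == 215.0
        assert not match.colocalised[0]
        just_inside = match_directed(src, make_map([(11.99, 10.0)], channel="b"),
                                     cfg60.threshold_nm)
        assert just_inside.colocalised[0]

    def test_empty_target_all_unmatched(self, random_map_factory, cfg60):
        src = random_map_factory(10, seed=2)
        tgt = make_map(np.empty((0, 2)), channel="b")
        match = match_directed(src, tgt, cfg60.threshold_nm)
        assert not match.colocalised.any()
        assert np.all(np.isinf(match.nearest_nm))

    def test_matches_brute_force_on_random_instances(self, random_map_factory, cfg60):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            src = random_map_factory(int(rng.integers(1, 51)), seed=2 * seed)
            tgt = random_map_factory(int(rng.integers(1, 51)), seed=2 * seed + 1,
                                     channel="b")
            match = match_directed(src, tgt, cfg60.threshold_nm)
            flags, dists = brute_force_flags(src, tgt, cfg60.threshold_nm)
            np.testing.assert_array_equal(match.colocalised, flags)
            np.testing.assert_allclose(match.nearest_nm, dists, rtol=1e-12)

    def test_mismatched_pixel_sizes_rejected(self, cfg60):
        src = make_map([(1.0, 1.0)], pixel_size_nm=107.5)
        tgt = make_map([(1.0, 1.0)], channel="b", pixel_size_nm=64.5)
        with pytest.raises(ColocError, match="pixel size"):
            match_directed(src, tgt, cfg60.threshold_nm)


class TestPercent:
    def test_counting_arithmetic(self, cfg60):
        src = make_map([(0, 0), (10, 0), (20, 0), (30, 0)])
        tgt = make_map([(0.5, 0), (10.5, 0), (20.5, 0)], channel="b")
        match = match_directed(src, tgt, cfg60.threshold_nm)
        assert percent_colocalised(match) == 75.0

    def test_all_and_none(self, random_map_factory, cfg60):
        m = random_map_factory(12, seed=3)
        assert percent_colocalised(match_directed(m, m, cfg60.threshold_nm)) == 100.0
        far = make_map(m.xy + 100.0, channel="b")
        assert percent_colocalised(match_directed(m, far, cfg60.threshold_nm)) == 0.0

    def test_empty_source_is_an_error_not_zero(self, random_map_factory, cfg60):
        src = make_map(np.empty((0, 2)))
        tgt = random_map_factory(5, seed=4, channel="b")
        match = match_directed(src, tgt, cfg60.threshold_nm)
        with pytest.raises(ColocError, match="undefined"):
            percent_colocalised(match)


class TestScramble:
    def test_preserves_count_and_brightness(self, random_map_factory):
        m = random_map_factory(37, seed=5)
        s = scramble_map(m, magnitude_px=20.0, rng=0)
        assert len(s) == 37
        np.testing.assert_array_equal(s.brightness, m.brightness)

    def test_fixed_seed_reproducible(self, random_map_factory):
        m = random_map_factory(20, seed=6)
        a = scramble_map(m, 20.0, rng=42)
        b = scramble_map(m, 20.0, rng=42)
        np.testing.assert_array_equal(a.xy, b.xy)

    def test_positions_stay_inside_bounds(self, random_map_factory):
        m = random_map_factory(50, seed=7, field_shape=(64, 64))
        s = scramble_map(m, magnitude_px=200.0, rng=1)
        assert np.all(s.xy >= -0.5) and np.all(s.xy <= 63.5)

    def test_scramble_destroys_colocalisation_to_chance(self, cfg60):
        """With a magnitude large relative to the inter-particle spacing,
        scrambling a copy of the source map drops colocalisation from 100%
        to the CSR chance level 100*(1 - exp(-rho*pi*tau^2)).  (At small
        magnitudes a particle stays within a 2m x 2m box of its original,
        leaving a residual ~pi*tau^2/(2m)^2 self-correlation term.)"""
        rng = np.random.default_rng(8)
        n, L = 300, 512
        src = make_map(rng.uniform(-0.5, L - 0.5, size=(n, 2)), field_shape=(L, L))
        tau_px = cfg60.threshold_px
        rho = n / L**2
        expect = 100.0 * (1.0 - np.exp(-rho * np.pi * tau_px**2))
        vals = []
        g = np.random.default_rng(9)
        for _ in range(60):
            s = scramble_map(src, magnitude_px=150.0, rng=g)
            s.channel = "b"
            vals.append(percent_colocalised(match_directed(src, s, cfg60.threshold_nm)))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expect) < 3 * se + 0.05

    def test_scrambling_source_or_target_equivalent_in_expectation(
        self, random_map_factory, cfg60
    ):
        src = random_map_factory(200, seed=10, field_shape=(512, 512))
        tgt = random_map_factory(200, seed=11, channel="b", field_shape=(512, 512))
        g = np.random.default_rng(12)
        a = [percent_colocalised(match_directed(src, scramble_map(tgt, 20, g),
                                                cfg60.threshold_nm))
             for _ in range(40)]
        b = [percent_colocalised(match_directed(scramble_map(src, 20, g), tgt,
                                                cfg60.threshold_nm))
             for _ in range(40)]
        a, b = np.array(a), np.array(b)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se + 0.1


class TestNetColocalisation:
    def test_independent_csr_maps_net_near_zero(self, random_map_factory, cfg60):
        nets = []
        for seed in range(8):
            src = random_map_factory(150, seed=100 + seed, field_shape=(512, 512))
            tgt = random_map_factory(150, seed=200 + seed, channel="b",
                                     field_shape=(512, 512))
            res = net_colocalisation([src, tgt], cfg60, n_repeats=30, seed=seed)
            nets.append(res.pair("a", "b").net_percent)
        nets = np.array(nets)
        se = nets.std(ddof=1) / np.sqrt(len(nets))
        assert abs(nets.mean()) < 3 * se + 0.1

    def test_identical_maps_raw_100_net_positive(self, random_map_factory, cfg60):
        m = random_map_factory(100, seed=13, field_shape=(512, 512))
        m2 = make_map(m.xy, channel="b", field_shape=(512, 512))
        res = net_colocalisation([m, m2], cfg60, n_repeats=20, seed=1)
        pair = res.pair("a", "b")
        assert pair.raw_percent == 100.0
        assert pair.net_percent > 90.0  # 100 minus a ~1% chance level
        assert pair.net_percent == pair.raw_percent - pair.scrambled_mean

    def test_directionality_differs_for_asymmetric_maps(self, cfg60):
        # 2 of 3 a-particles near b's; only 2 of 40 b-particles near a's
        rng = np.random.default_rng(14)
        a_xy = np.array([(50.0, 50.0), (100.0, 100.0), (150.0, 150.0)])
        b_xy = np.vstack([
            a_xy[:2] + 0.5,
            rng.uniform(180, 250, size=(38, 2)),
        ])
        res = net_colocalisation(
            [make_map(a_xy), make_map(b_xy, channel="b")], cfg60,
            n_repeats=5, seed=2,
        )
        ab = res.pair("a", "b").raw_percent
        ba = res.pair("b", "a").raw_percent
        assert ab == pytest.approx(100 * 2 / 3)
        assert ba == pytest.approx(100 * 2 / 40)

    def test_rigid_motion_invariance(self, random_map_factory, cfg60):
        src = random_map_factory(80, seed=15, field_shape=(512, 512))
        tgt = random_map_factory(80, seed=16, channel="b", field_shape=(512, 512))
        raw0 = percent_colocalised(match_directed(src, tgt, cfg60.threshold_nm))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t = np.array([31.4, -12.0])
        src2 = src.with_positions(src.xy @ R.T + t)
        tgt2 = tgt.with_positions(tgt.xy @ R.T + t)
        raw1 = percent_colocalised(match_directed(src2, tgt2, cfg60.threshold_nm))
        assert raw0 == raw1

    def test_threshold_monotonicity(self, random_map_factory):
        src = random_map_factory(60, seed=17)
        tgt = random_map_factory(60, seed=18, channel="b")
        percents = [
            percent_colocalised(match_directed(src, tgt, t_nm))
            for t_nm in np.linspace(20, 2000, 20)
        ]
        assert np.all(np.diff(percents) >= 0)

    def test_empty_channel_reported_undefined_with_warning(self, random_map_factory, cfg60):
        src = random_map_factory(10, seed=19)
        empty = make_map(np.empty((0, 2)), channel="b")
        with pytest.warns(UserWarning, match="empty"):
            res = net_colocalisation([src, empty], cfg60, n_repeats=2, seed=0)
        assert res.pair("a", "b") is None
        assert res.pair("b", "a") is None

    def test_report_round_trip_and_provenance(self, random_map_factory, cfg60, tmp_path):
        import json

        src = random_map_factory(40, seed=20)
        tgt = random_map_factory(40, seed=21, channel="b")
        res = net_colocalisation([src, tgt], cfg60, n_repeats=5, seed=77)
        res.to_json(tmp_path / "report.json")
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["seed"] == 77
        assert payload["threshold_nm"] == 215.0
        assert set(payload["pairs"]) == {"a->b", "b->a"}
        df = res.to_frame()
        assert set(df["pair"]) == {"a->b", "b->a"}


class TestMultiChannel:
    def test_triple_positive_is_conjunction(self, cfg60):
        a = make_map([(10.0, 10.0), (50.0, 50.0)])
        b = make_map([(10.5, 10.0)], channel="b")
        c = make_map([(10.0, 10.5), (50.5, 50.0)], channel="c")
        table = multi_colocalised([a, b, c], cfg60.threshold_nm)
        assert list(table["b"]) == [True, False]
        assert list(table["c"]) == [True, True]
        assert list(table["all_channels"]) == [True, False]

    def test_requires_three_channels(self, random_map_factory, cfg60):
        with pytest.raises(ColocError):
            multi_colocalised(
                [random_map_factory(3, seed=0), random_map_factory(3, seed=1, channel="b")],
                cfg60.threshold_nm,
            )

    def test_matches_per_pair_brute_force(self, random_map_factory, cfg60):
        for seed in range(10):
            maps = [
                random_map_factory(20 + 5 * k, seed=300 + 3 * seed + k, channel=ch)
                for k, ch in enumerate(("a", "b", "c"))
            ]
            table = multi_colocalised(maps, cfg60.threshold_nm)
            for m in maps[1:]:
                flags, _ = brute_force_flags(maps[0], m, cfg60.threshold_nm)
                np.testing.assert_array_equal(table[m.channel].to_numpy(), flags)


def ray_cast_inside(vertices, point):
    """Independent even-odd point-in-polygon oracle."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestRoi:
    SQUARE = np.array([(10.0, 10.0), (60.0, 10.0), (60.0, 60.0), (10.0, 60.0)])

    def test_centroid_of_convex_roi_retained(self):
        roi = RoiPolygon(self.SQUARE)
        m = make_map([(35.0, 35.0)])
        assert len(filter_roi(m, roi)) == 1

    def test_point_outside_bounding_box_removed(self):
        roi = RoiPolygon(self.SQUARE)
        m = make_map([(200.0, 200.0)])
        assert len(filter_roi(m, roi)) == 0

    def test_boundary_point_excluded(self):
        roi = RoiPolygon(self.SQUARE)
        m = make_map([(10.0, 35.0)])
        assert len(filter_roi(m, roi)) == 0

    def test_matches_ray_casting_oracle(self, random_map_factory):
        verts = np.array(
            [(20.0, 10.0), (90.0, 25.0), (70.0, 80.0), (45.0, 55.0), (15.0, 70.0)]
        )
        roi = RoiPolygon(verts)
        m = random_map_factory(300, seed=22, field_shape=(100, 100))
        kept = roi.contains(m.xy)
        expected = np.array([ray_cast_inside(verts, p) for p in m.xy])
        np.testing.assert_array_equal(kept, expected)

    @pytest.mark.parametrize(
        "verts",
        [
            [(0, 0), (1, 1)],  # too few vertices
            [(0, 0), (2, 2), (2, 0), (0, 2)],  # bow-tie self-intersection
            [(0, 0), (1, 0), (2, 0)],  # collinear, zero area
        ],
    )
    def test_degenerate_polygons_rejected(self, verts):
        with pytest.raises(ColocError):
            RoiPolygon(np.array(verts, float))

    def test_roi_restricts_net_colocalisation(self, random_map_factory, cfg60):
        roi = RoiPolygon(np.array([(0.0, 0.0), (128.0, 0.0), (128.0, 128.0), (0.0, 128.0)]))
        src = random_map_factory(200, seed=23, field_shape=(256, 256))
        tgt = random_map_factory(200, seed=24, channel="b", field_shape=(256, 256))
        res = net_colocalisation([src, tgt], cfg60, n_repeats=3, seed=0, roi=roi)
        pair = res.pair("a", "b")
        assert pair.n_source < 200
        assert res.roi_label == "roi"
        inside = roi.contains(src.xy).sum()
        assert pair.n_source == inside


class TestAggregation:
    def _result(self, factory, cfg, n, seed):
        src = factory(n, seed=seed, field_shape=(256, 256))
        tgt = factory(n, seed=seed + 1000, channel="b", field_shape=(256, 256))
        return net_colocalisation([src, tgt], cfg, n_repeats=4, seed=seed)

    def test_pooled_weights_by_particle_counts(self, random_map_factory, cfg60):
        r1 = self._result(random_map_factory, cfg60, 20, 25)
        r2 = self._result(random_map_factory, cfg60, 80, 26)
        agg = aggregate_cells([r1, r2], mode="pooled")
        p1, p2 = r1.pair("a", "b"), r2.pair("a", "b")
        pooled = agg.pair("a", "b")
        assert pooled.n_source == 100
        assert pooled.raw_percent == pytest.approx(
            100.0 * (p1.n_flagged + p2.n_flagged) / 100
        )

    def test_mean_mode_averages_percentages(self, random_map_factory, cfg60):
        r1 = self._result(random_map_factory, cfg60, 20, 27)
        r2 = self._result(random_map_factory, cfg60, 80, 28)
        agg = aggregate_cells([r1, r2], mode="mean")
        p1, p2 = r1.pair("a", "b"), r2.pair("a", "b")
        assert agg.pair("a", "b").raw_percent == pytest.approx(
            (p1.raw_percent + p2.raw_percent) / 2
        )
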