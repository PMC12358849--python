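"""High-order domain segmentation, tracking and null-model tests."""

import numpy as np
import pytest

import oracles
from fiberorder import (
    Mask,
    OrderField,
    domain_metrics,
    high_order_domains,
    homogeneous_null,
    track_domains,
)
from fiberorder.domains import DomainLabelMap, fusion_frames


def _field(S, px=1.0):
    return OrderField(np.asarray(S, dtype=float), window_um=10.0, pixel_size_um=px)


def _disk(shape, center, radius):
    y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (y - center[0]) ** 2 + (x - center[1]) ** 2 <= radius**2


class TestHighOrderDomains:
    def test_uniform_high_field_single_domain(self, full_mask):
        lm = high_order_domains(_field(np.full((32, 32), 0.9)), full_mask((32, 32)),
                                0.6, 25)
        assert lm.n_domains == 1
        assert np.all(lm.labels == 1)

    def test_two_disks_give_two_domains_with_expected_diameters(self, full_mask):
        S = np.full((96, 96), 0.2)
        d1 = _disk((96, 96), (30, 30), 12)
        d2 = _disk((96, 96), (65, 65), 8)
        S[d1] = 0.9
        S[d2] = 0.9
        lm = high_order_domains(_field(S), full_mask((96, 96)), 0.6, 25)
        table, summary = domain_metrics(lm)
        assert summary["n_domains"] == 2
        for area in (d1.sum(), d2.sum()):
            expect = 2 * np.sqrt(area / np.pi)
            assert np.any(np.abs(table["equivalent_diameter_um"] - expect) < 1e-9)
        # labels ordered by decreasing area
        assert table["area_px"].is_monotonic_decreasing

    def test_small_blob_removed(self, full_mask):
        S = np.full((32, 32), 0.2)
        S[10:13, 10:13] = 0.9  # 9 px < min_area 25
        lm = high_order_domains(_field(S), full_mask((32, 32)), 0.6, 25)
        assert lm.n_domains == 0

    def test_threshold_monotonicity_no_growth_no_merge(self, full_mask):
        from scipy import ndimage

        rng = np.random.default_rng(7)
        S = ndimage.gaussian_filter(rng.random((64, 64)), 4)
        S = (S - S.min()) / (S.max() - S.min())
        mask = full_mask((64, 64))
        low = high_order_domains(_field(S), mask, 0.5, 1)
        high = high_order_domains(_field(S), mask, 0.7, 1)
        assert (high.labels > 0).sum() <= (low.labels > 0).sum()
        # every high-threshold domain sits inside exactly one low-threshold domain
        for h in range(1, high.n_domains + 1):
            parents = set(np.unique(low.labels[high.labels == h]))
            assert len(parents - {0}) == 1 and 0 not in parents

    def test_threshold_validation(self, full_mask):
        with pytest.raises(ValueError, match="threshold"):
            high_order_domains(_field(np.ones((8, 8))), full_mask((8, 8)), 1.5, 1)


class TestDomainMetrics:
    def test_equivalent_diameter_formula(self, full_mask):
        S = np.full((32, 32), 0.2)
        S[:10, :10] = 0.9  # area 100 px
        lm = high_order_domains(_field(S), full_mask((32, 32)), 0.6, 25)
        table, summary = domain_metrics(lm)
        assert table["equivalent_diameter_um"][0] == pytest.approx(
            2 * np.sqrt(100 / np.pi)
        )
        assert summary["mean_diameter_um"] == pytest.approx(11.2838, abs=1e-3)

    def test_zero_domains_mean_diameter_missing(self, full_mask):
        lm = high_order_domains(_field(np.full((16, 16), 0.1)), full_mask((16, 16)),
                                0.6, 25)
        _, summary = domain_metrics(lm)
        assert summary["n_domains"] == 0
        assert np.isnan(summary["mean_diameter_um"])

    def test_high_order_fraction_bounded(self, full_mask):
        S = np.full((32, 32), 0.9)
        mask = full_mask((32, 32))
        lm = high_order_domains(_field(S), mask, 0.6, 25)
        _, summary = domain_metrics(lm, mask)
        assert summary["total_high_order_fraction"] == pytest.approx(1.0)


class TestTracking:
    def _label_map(self, labels):
        return DomainLabelMap(np.asarray(labels, dtype=int), 0.6, 1, 1.0)

    def test_identical_frames_identity_lineage(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[2:8, 2:8] = 1
        track = track_domains([self._label_map(labels)] * 3)
        assert track.events == []
        assert all(links == {1: {1}} for links in track.lineage)

    def test_fusion_event_detected(self):
        a = np.zeros((16, 32), dtype=int)
        a[6:10, 4:10] = 1
        a[6:10, 20:26] = 2
        b = np.zeros((16, 32), dtype=int)
        b[6:10, 4:26] = 1
        track = track_domains([self._label_map(a), self._label_map(b)])
        assert (1, "fusion", (1, 2, 1)) in track.events
        assert fusion_frames(track) == [1]

    def test_death_and_birth_events(self):
        a = np.zeros((16, 16), dtype=int)
        a[2:6, 2:6] = 1
        empty = np.zeros((16, 16), dtype=int)
        track = track_domains([self._label_map(a), self._label_map(empty)])
        assert (1, "death", (1,)) in track.events
        track2 = track_domains([self._label_map(empty), self._label_map(a)])
        assert (1, "birth", (1,)) in track2.events

    def test_split_event_detected(self):
        a = np.zeros((16, 32), dtype=int)
        a[6:10, 4:26] = 1
        b = np.zeros((16, 32), dtype=int)
        b[6:10, 4:10] = 1
        b[6:10, 20:26] = 2
        track = track_domains([self._label_map(a), self._label_map(b)])
        assert any(kind == "split" for _, kind, _ in track.events)

    def test_lineage_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        maps = []
        for _ in range(4):
            from scipy import ndimage

            S = ndimage.gaussian_filter(rng.random((32, 32)), 3)
            binary = S > np.percentile(S, 70)
            labels, _ = ndimage.label(binary, structure=np.ones((3, 3), int))
            maps.append(self._label_map(labels))
        track = track_domains(maps, min_overlap_frac=0.3)
        for t in range(3):
            ref = oracles.lineage_bruteforce(maps[t].labels, maps[t + 1].labels, 0.3)
            assert track.lineage[t] == ref

    def test_requires_two_frames(self):
        with pytest.raises(ValueError, match="2 frames"):
            track_domains([self._label_map(np.zeros((8, 8), int))])


class TestHomogeneousNull:
    def test_constant_field_null_is_exactly_homogeneous(self, full_mask):
        field = _field(np.full((32, 32), 0.5))
        res = homogeneous_null(field, np.array([0.5, 0.65, 0.7]), full_mask((32, 32)))
        for fld, target in zip(res.null_fields, [0.5, 0.65, 0.7]):
            vals = fld.S[np.isfinite(fld.S)]
            assert np.ptp(vals) == 0.0
            assert vals[0] == pytest.approx(target)

    def test_null_mean_matches_trajectory_before_clipping(self, full_mask):
        rng = np.random.default_rng(1)
        S = 0.2 + 0.4 * rng.random((32, 32))  # far from clip bounds
        field = _field(S)
        m0 = S.mean()
        traj = np.array([m0, m0 + 0.1, m0 + 0.15])
        res = homogeneous_null(field, traj, full_mask((32, 32)))
        np.testing.assert_allclose(
            res.comparison["null_mean_postclip"], traj, atol=1e-9
        )

    def test_clipping_recomputes_reported_mean(self, full_mask):
        S = np.full((16, 16), 0.95)
        field = _field(S)
        res = homogeneous_null(field, np.array([0.95, 1.05]), full_mask((16, 16)))
        last = res.null_fields[-1].S
        assert np.nanmax(last) == 1.0
        assert res.comparison["null_mean_postclip"].iloc[-1] == pytest.approx(1.0)

    def test_decreasing_trajectory_allowed(self, full_mask):
        field = _field(np.full((16, 16), 0.5))
        res = homogeneous_null(field, np.array([0.5, 0.3]), full_mask((16, 16)))
        assert res.comparison["null_mean_postclip"].iloc[-1] == pytest.approx(0.3)

    def test_trajectory_must_start_at_initial_mean(self, full_mask):
        field = _field(np.full((16, 16), 0.5))
        with pytest.raises(ValueError, match="start at"):
            homogeneous_null(field, np.array([0.6, 0.7]), full_mask((16, 16)))

    def test_localized_growth_beats_null_diameters(self, full_mask):
        from fiberorder import make_time_series

        init = np.zeros((128, 128), dtype=int)
        for i, (r, c) in enumerate([(40, 40), (40, 88), (88, 64)], start=1):
            init[_disk((128, 128), (r, c), 5)] = i
        ts = make_time_series(init, 3.0, 0.8, 0.3, 6, seed=2, render_images=False)
        mask = full_mask((128, 128))
        fields = [_field(gt.order_map) for _, gt in ts.frames]
        means = np.array([f.S.mean() for f in fields])
        obs = []
        for f in fields:
            _, summary = domain_metrics(high_order_domains(f, mask, 0.6, 25), mask)
            obs.append(summary["mean_diameter_um"])
        res = homogeneous_null(fields[0], means, mask,
                               observed_mean_diameter_um=np.array(obs))
        tail = res.comparison.iloc[2:]
        assert np.all(
            tail["observed_mean_diameter_um"] > tail["null_mean_diameter_um"]
        )
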