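"""Fragment filters and viewpoint-window normalization."""

import numpy as np
import pytest

import fourc
from conftest import build_map


class TestViewpoint:
    def test_parse(self):
        vp = fourc.Viewpoint.parse("chr10:54427977-54428133")
        assert (vp.chrom, vp.start, vp.end) == ("chr10", 54427977, 54428133)
        assert vp.centre == (54427977 + 54428133) // 2

    def test_invariants(self):
        with pytest.raises(ValueError):
            fourc.Viewpoint("c", 10, 10)
        with pytest.raises(ValueError):
            fourc.Viewpoint("c", 0, 10, exclusion_radius=0)
        with pytest.raises(ValueError):
            fourc.Viewpoint("c", 0, 10, exclusion_radius=10_000, norm_radius=5_000)


class TestApplyFilters:
    def test_toy_map_rules_and_report(self, toy_map, toy_vp):
        rc = fourc.RawCounts(fmap=toy_map, counts=np.arange(1, 7))
        filtered, report = fourc.apply_filters(rc, toy_vp, min_len=40)
        assert report.retained == 2
        assert report.removed_class == 2  # one blind + one terminal
        assert report.removed_length == 1
        assert report.removed_proximity == 1
        assert report.removed_total + report.retained == len(toy_map)
        kept = toy_map.df.index[filtered.retained].tolist()
        assert kept == [0, 4]

    def test_disabled_filters_leave_only_class_rule(self, toy_map, toy_vp):
        rc = fourc.RawCounts(fmap=toy_map, counts=np.ones(6, dtype=int))
        vp = fourc.Viewpoint(toy_vp.chrom, toy_vp.start, toy_vp.end, exclusion_radius=1)
        _, report = fourc.apply_filters(rc, vp, min_len=0)
        assert report.removed_length == 0 and report.removed_proximity == 0
        assert report.removed_class == 2

    def test_all_pass_when_everything_qualifies(self):
        fmap = build_map(
            [
                ("chrT", 0, 100, "primary", "secondary"),
                ("chrT", 100, 200, "secondary", "primary"),
            ]
        )
        vp = fourc.Viewpoint("chrT", 195, 200, exclusion_radius=60, norm_radius=1000)
        rc = fourc.RawCounts(fmap=fmap, counts=np.array([1, 1]))
        _, report = fourc.apply_filters(rc, vp, min_len=40)
        assert report.removed_total == 1  # only the near-viewpoint fragment
        # with a distant viewpoint nothing is removed
        vp_far = fourc.Viewpoint("chrT", 195, 200, exclusion_radius=1, norm_radius=1000)
        _, report2 = fourc.apply_filters(rc, vp_far, min_len=40)
        assert report2.removed_total == 0

    def test_idempotence(self, toy_map, toy_vp):
        rc = fourc.RawCounts(fmap=toy_map, counts=np.arange(1, 7))
        once, rep1 = fourc.apply_filters(rc, toy_vp)
        twice, rep2 = fourc.apply_filters(once, toy_vp)
        assert (once.retained == twice.retained).all()
        assert rep1.to_dict() == rep2.to_dict()

    def test_missing_viewpoint_chromosome(self, toy_map):
        rc = fourc.RawCounts(fmap=toy_map, counts=np.ones(6, dtype=int))
        with pytest.raises(ValueError, match="absent"):
            fourc.apply_filters(rc, fourc.Viewpoint("chrZ", 0, 100))


class TestNormalize:
    def _profile(self, counts, target):
        fmap = build_map(
            [
                ("chrT", 0, 100, "primary", "secondary"),
                ("chrT", 100, 200, "secondary", "primary"),
                ("chrT", 200, 300, "primary", "secondary"),
            ]
        )
        vp = fourc.Viewpoint("chrT", 99, 101, exclusion_radius=1, norm_radius=120)
        rc = fourc.RawCounts(fmap=fmap, counts=np.asarray(counts))
        filtered, _ = fourc.apply_filters(rc, vp, min_len=0)
        return fourc.normalize(filtered, target_total=target)

    def test_already_normalized(self):
        # all three midpoints (50, 150, 250): only 50 and 150 are in ±120
        prof = self._profile([2, 3, 5], target=5.0)
        assert prof.window_weight == 5.0
        np.testing.assert_allclose(prof.signal, [2, 3, 5])

    def test_out_of_window_fragment_scaled_but_not_counted(self):
        prof = self._profile([1, 1, 7], target=1.0)
        np.testing.assert_allclose(prof.signal, [0.5, 0.5, 3.5])

    def test_single_in_window_fragment(self):
        fmap = build_map([("chrT", 0, 100, "primary", "secondary")])
        vp = fourc.Viewpoint("chrT", 0, 4, exclusion_radius=1, norm_radius=100)
        rc = fourc.RawCounts(fmap=fmap, counts=np.array([4]))
        filtered, _ = fourc.apply_filters(rc, vp, min_len=0)
        prof = fourc.normalize(filtered, target_total=1e6)
        assert prof.signal[0] == pytest.approx(1e6)

    def test_zero_window_weight_is_hard_error(self):
        with pytest.raises(ValueError, match="no signal"):
            self._profile([0, 0, 7], target=1.0)

    def test_conservation_and_scale_equivariance(self, map5m, vp5m):
        rng = np.random.default_rng(42)
        for _ in range(20):
            counts = rng.integers(0, 50, size=len(map5m))
            rc = fourc.RawCounts(fmap=map5m, counts=counts)
            filtered, _ = fourc.apply_filters(rc, vp5m)
            prof = fourc.normalize(filtered)
            in_win = prof.in_window()
            assert prof.signal[in_win].sum() == pytest.approx(1e6, rel=1e-9)
            # multiplying raw counts by k>0 leaves the profile unchanged
            rc_k = fourc.RawCounts(fmap=map5m, counts=counts * 3)
            filtered_k, _ = fourc.apply_filters(rc_k, vp5m)
            prof_k = fourc.normalize(filtered_k)
            np.testing.assert_allclose(prof_k.signal, prof.signal, rtol=1e-12)
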