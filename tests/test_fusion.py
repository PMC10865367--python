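import numpy as np
import pytest
from scipy import ndimage as ndi

import segfuse as sf
from segfuse import (
    BinaryMask,
    FusionConfig,
    SegmentationSet,
    extract_line,
    fill_holes,
    fuse,
    fuse_avg_smallest_largest,
    fuse_avg_target,
    fuse_largest,
    fuse_middle,
    fuse_smallest,
    fuse_staple,
    is_closed,
)
from segfuse.errors import (
    ConfigError,
    EmptyIntersectionError,
    RegistrationError,
)
from segfuse.fusion import group_consensus, nearest_member, register_algorithm

from conftest import disk, square


def set_of(*arrays):
    return SegmentationSet(tuple(BinaryMask(a) for a in arrays))


def radii_of(line, center):
    rr, cc = np.nonzero(line.pixels)
    return np.hypot(rr - center[0], cc - center[1])


class TestLargestSmallest:
    def test_nested_squares(self, nested_squares):
        out = fuse_largest(nested_squares, line_mode="internal")
        expected = square(13, 2, 2, 9) & ~square(13, 3, 3, 7)
        assert (out.pixels == expected).all()
        out = fuse_smallest(nested_squares, line_mode="internal")
        expected = square(13, 4, 4, 5) & ~square(13, 5, 5, 3)
        assert (out.pixels == expected).all()

    def test_overlapping_disks_union_matches_boundary_scan(self):
        a = disk(48, (24, 18), 10)
        b = disk(48, (24, 30), 10)
        out = fuse_largest(set_of(a, b), line_mode="internal")
        union = a | b  # oracle: boolean OR + boundary scan
        boundary = union & ~ndi.binary_erosion(
            union, structure=ndi.generate_binary_structure(2, 1), border_value=0
        )
        assert (out.pixels == boundary).all()

    def test_identical_inputs_idempotent(self):
        a = disk(48, (24, 24), 12)
        for fn in (fuse_largest, fuse_smallest):
            out = fn(set_of(a, a, a), line_mode="internal")
            assert (fill_holes(out).pixels == a).all()

    def test_disjoint_disks(self):
        a = disk(48, (12, 12), 6)
        b = disk(48, (34, 34), 6)
        with pytest.raises(EmptyIntersectionError):
            fuse_smallest(set_of(a, b))


class TestAvgSmallestLargest:
    def test_nested_disks_midline(self):
        segs = set_of(disk(64, (32, 32), 6), disk(64, (32, 32), 10))
        out = fuse_avg_smallest_largest(segs)
        r = radii_of(out, (32, 32))
        band = disk(64, (32, 32), 10) & ~ndi.binary_erosion(
            disk(64, (32, 32), 6), structure=ndi.generate_binary_structure(2, 1)
        )
        yy, xx = np.mgrid[:64, :64]
        rad = np.hypot(yy - 32, xx - 32)
        midline = (rad[band].min() + rad[band].max()) / 2  # distance-ridge oracle
        assert np.all(np.abs(r - midline) <= 1.0)
        assert is_closed(out)

    def test_nested_squares_ring(self):
        segs = set_of(square(13, 4, 4, 5), square(13, 2, 2, 9))
        out = fuse_avg_smallest_largest(segs)
        # midline of the band between the 5x5 and 9x9 squares: the 7x7 ring
        rr, cc = np.nonzero(out.pixels)
        cheb = np.maximum(np.abs(rr - 6), np.abs(cc - 6))
        assert np.all(np.abs(cheb - 3) <= 1)
        assert is_closed(out)

    def test_identical_inputs_returns_perimeter(self):
        a = disk(48, (24, 24), 12)
        out = fuse_avg_smallest_largest(set_of(a, a), line_mode="internal")
        assert (fill_holes(out).pixels == a).all()

    def test_sandwich_between_smallest_and_largest(self, boundary_set):
        fused = fill_holes(fuse_avg_smallest_largest(boundary_set)).pixels
        small = fill_holes(fuse_smallest(boundary_set, line_mode="internal")).pixels
        large = fill_holes(fuse_largest(boundary_set, line_mode="internal")).pixels
        cross = ndi.generate_binary_structure(2, 1)
        assert (ndi.binary_erosion(small, cross) <= fused).all()
        assert (fused <= ndi.binary_dilation(large, cross)).all()


class TestPixelGroups:
    def test_nearest_member_basic_and_ties(self):
        line = sf.ContourLine(np.zeros((8, 8), bool) | _px((2, 2), (5, 5)))
        assert nearest_member((0, 0), line) == (2, 2)
        tie = sf.ContourLine(_px((0, 3), (3, 0)))
        assert nearest_member((0, 0), tie) == (0, 3)  # smallest row wins
        on = sf.ContourLine(_px((2, 2), (5, 5)))
        assert nearest_member((5, 5), on) == (5, 5)

    def test_group_consensus_rules(self):
        assert group_consensus([(0, 0), (2, 2)]) == (1.0, 1.0)
        assert group_consensus([(0, 0), (1, 1), (4, 4)]) == (2.0, 2.0)
        assert group_consensus([(0, 0), (0, 2), (2, 0), (2, 2)]) == (1.0, 1.0)
        # duplicates of a single point collapse to it
        assert group_consensus([(3, 4)] * 4) == (3.0, 4.0)


class TestAvgTarget:
    def test_concentric_circles_target_largest(self):
        segs = set_of(disk(64, (31.5, 31.5), 6.5), disk(64, (31.5, 31.5), 10.5))
        out = fuse_avg_target(segs, target="largest", line_mode="internal")
        r = radii_of(out, (31.5, 31.5))
        assert np.all(np.abs(r - 8.0) <= 1.5)

    def test_identical_inputs_return_input_contour(self):
        # every group collapses to one point, so the consensus cloud is the
        # input contour itself; re-closing it may add a pixel or two of
        # rasterization noise but the enclosed region is preserved
        a = disk(48, (24, 24), 12)
        segs = set_of(a, a, a)
        out = fuse_avg_target(segs, target="largest", line_mode="internal")
        contour = extract_line(BinaryMask(a), mode="internal")
        assert (contour.pixels <= out.pixels).all()  # contour pixels all kept
        assert sf.jaccard(out, a).value >= 0.99

    def test_bad_target_index(self):
        a = disk(48, (24, 24), 12)
        with pytest.raises(ConfigError):
            fuse_avg_target(set_of(a, a), target="input", target_index=3)


class TestMiddle:
    def _nested(self, *radii):
        return set_of(*[disk(64, (32, 32), r) for r in radii])

    def test_three_nested_picks_median_bit_exactly(self):
        segs = self._nested(6, 9, 12)
        out = fuse_middle(segs, line_mode="internal")
        expected = extract_line(segs[1], mode="internal")
        assert (out.pixels == expected.pixels).all()

    def test_six_inputs_two_removal_iterations(self):
        info = {}
        segs = self._nested(4, 6, 8, 10, 12, 14)
        fuse_middle(segs, tiebreak="average", line_mode="internal", info=info)
        assert info["iterations"] == 2  # floor((6-1)/2)
        assert info["survivors"] == [3, 4]  # the two median raters

    def test_two_inputs_average_equals_avg_smallest_largest(self):
        segs = self._nested(7, 11)
        a = fuse_middle(segs, tiebreak="average", line_mode="internal")
        b = fuse_avg_smallest_largest(segs, line_mode="internal")
        assert (a.pixels == b.pixels).all()

    def test_area_tie_removes_lowest_index(self):
        a = disk(64, (32, 28), 8)
        b = disk(64, (32, 36), 8)  # same area as a
        c = disk(64, (32, 32), 12)
        info = {}
        fuse_middle(set_of(a, b, c), line_mode="internal", info=info)
        assert info["survivors"] == [2]  # rater 1 removed as the area tie


class TestStaple:
    def test_identical_inputs_exact(self):
        a = disk(48, (24, 24), 12)
        out = fuse_staple(set_of(a, a, a), line_mode="internal")
        assert (fill_holes(out).pixels == a).all()

    def test_two_against_one_complement(self):
        # oracle: per-pixel posterior for this vote pattern. The two agreeing
        # raters get sensitivity/specificity ~1 against the majority vote,
        # the complement rater ~0, so the consensus equals the majority pair.
        region = disk(32, (16, 16), 8)
        votes = np.stack([region, region, ~region]).reshape(3, -1)
        res = sf.staple_em(votes)
        assert ((res.weights >= 0.5).reshape(32, 32) == region).all()

    def test_parameter_recovery_and_sitk_cross_check(self, disk_truth=None):
        import SimpleITK as sitk

        truth = sf.make_shape(sf.ShapeSpec(kind="disk", canvas=(128, 128), radius=30))
        votes = np.stack(
            [sf.bernoulli_votes(truth, 0.90, 0.98, seed=j) for j in range(5)]
        )
        res = sf.staple_em(votes.reshape(5, -1))
        assert np.all(np.abs(res.performance.sensitivity - 0.90) <= 0.05)
        assert np.all(np.abs(res.performance.specificity - 0.98) <= 0.02)
        # independent implementation cross-check
        f = sitk.STAPLEImageFilter()
        f.SetForegroundValue(1)
        w = sitk.GetArrayFromImage(
            f.Execute([sitk.GetImageFromArray(v.astype(np.uint8)) for v in votes])
        )
        ours = (res.weights >= 0.5).reshape(128, 128)
        theirs = w >= 0.5
        assert sf.jaccard(ours, theirs).value >= 0.99
        assert np.all(np.abs(np.array(f.GetSensitivity()) - res.performance.sensitivity) <= 0.02)

    def test_majority_vote_reduction_symmetric_raters(self):
        # when all raters are statistically identical, the consensus matches
        # the majority vote (checked over several seeds)
        truth = sf.make_shape(sf.ShapeSpec(kind="disk", canvas=(64, 64), radius=15))
        agree = 0
        for seed in range(20):
            votes = np.stack(
                [sf.bernoulli_votes(truth, 0.85, 0.95, seed=seed * 7 + j) for j in range(5)]
            )
            res = sf.staple_em(votes.reshape(5, -1))
            consensus = (res.weights >= 0.5).reshape(64, 64)
            majority = votes.mean(axis=0) >= 0.5
            agree += sf.jaccard(consensus, majority).value >= 0.98
        assert agree >= 18


class TestDispatcherAndRegistry:
    def test_dispatch_and_unknown(self, nested_squares):
        out = fuse(nested_squares, FusionConfig(algorithm="largest", line_mode="internal"))
        assert (out.pixels == (square(13, 2, 2, 9) & ~square(13, 3, 3, 7))).all()
        with pytest.raises(ConfigError) as err:
            fuse(nested_squares, FusionConfig(algorithm="foo"))
        for name in sf.ALGORITHMS:
            assert name in str(err.value)

    def test_plugin_registration(self, nested_squares):
        def my_fusion(segs, cfg):
            return fuse_largest(segs, line_mode=cfg.line_mode)

        register_algorithm("test_plugin_alg", my_fusion, {"strength": int})
        try:
            out = fuse(
                nested_squares,
                FusionConfig(
                    algorithm="test_plugin_alg",
                    line_mode="internal",
                    extra={"strength": "3"},
                ),
            )
            assert is_closed(out)
            with pytest.raises(RegistrationError):
                register_algorithm("largest", my_fusion)
            with pytest.raises(ConfigError, match="strength"):
                fuse(
                    nested_squares,
                    FusionConfig(
                        algorithm="test_plugin_alg", extra={"strength": "lots"}
                    ),
                )
        finally:
            from segfuse.fusion import _REGISTRY

            _REGISTRY.pop("test_plugin_alg", None)

    def test_invalid_config_values(self):
        with pytest.raises(ConfigError):
            FusionConfig(line_mode="diagonal")
        with pytest.raises(ConfigError):
            FusionConfig(staple_threshold=1.5)


class TestPermutationAndNesting:
    @pytest.mark.parametrize("alg", ["largest", "smallest", "avg_smallest_largest", "staple"])
    def test_permutation_invariance(self, boundary_set, alg):
        cfg = FusionConfig(algorithm=alg, line_mode="internal")
        base = fuse(boundary_set, cfg)
        perm = SegmentationSet(tuple(boundary_set[i] for i in [3, 0, 4, 1, 2]))
        assert (fuse(perm, cfg).pixels == base.pixels).all()

    def test_middle_odd_permutation_invariance(self):
        # distinct areas: the median is unambiguous, so order cannot matter
        segs = set_of(*[disk(64, (32, 32), r) for r in (6, 8, 10, 12, 14)])
        cfg = FusionConfig(algorithm="middle", line_mode="internal")
        base = fuse(segs, cfg)
        perm = SegmentationSet(tuple(segs[i] for i in [4, 2, 0, 3, 1]))
        assert (fuse(perm, cfg).pixels == base.pixels).all()
        # odd N: the output is bit-identical to one input's contour
        candidates = [extract_line(m, mode="internal").pixels for m in segs]
        assert any((base.pixels == c).all() for c in candidates)

    def test_nesting_invariant(self, boundary_set):
        small = fill_holes(fuse_smallest(boundary_set, line_mode="internal")).pixels
        large = fill_holes(fuse_largest(boundary_set, line_mode="internal")).pixels
        for mask in boundary_set:
            filled = ndi.binary_fill_holes(mask.pixels)
            assert (small <= filled).all()
            assert (filled <= large).all()


def _px(*coords):
    arr = np.zeros((8, 8), dtype=bool)
    for r, c in coords:
        arr[r, c] = True
    return arr
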