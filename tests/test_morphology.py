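import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipcyte.morphology import (
    SievePredicate,
    StructuringElement,
    break_clumps,
    erode,
    fill_holes,
    sieve,
)
from chipcyte.segment import label_components
from oracles import brute_break_clumps, brute_erode, brute_fill_holes, brute_sieve


def disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestErode:
    def test_square_erosion_analytic(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        out = erode(mask, StructuringElement("square", 3))
        expected = np.zeros((9, 9), bool)
        expected[3:6, 3:6] = True
        np.testing.assert_array_equal(out, expected)

    def test_empty_mask(self):
        assert not erode(np.zeros((6, 6), bool), StructuringElement("square", 3)).any()

    def test_random_masks_match_neighbourhood_oracle(self, rng):
        se = StructuringElement("square", 3)
        for _ in range(20):
            mask = rng.random((16, 16)) < 0.6
            np.testing.assert_array_equal(erode(mask, se), brute_erode(mask, se.footprint()))

    def test_anti_extensive(self, rng):
        mask = rng.random((32, 32)) < 0.5
        assert (erode(mask, StructuringElement("disc", 5)) <= mask).all()


class TestFillHoles:
    def test_ring_becomes_solid_square(self):
        mask = np.zeros((7, 7), bool)
        mask[1:6, 1:6] = True
        mask[2:5, 2:5] = False  # enclosed hole
        out = fill_holes(mask)
        assert out[1:6, 1:6].all() and out.sum() == 25

    def test_open_bay_at_border_unchanged(self):
        mask = np.zeros((6, 6), bool)
        mask[2:5, 1:5] = True
        mask[3, 0:3] = False  # bay opening to the left border
        np.testing.assert_array_equal(fill_holes(mask), mask)

    def test_extensive_and_idempotent_on_random_masks(self, rng):
        for _ in range(100):
            mask = rng.random((20, 20)) < 0.5
            once = fill_holes(mask)
            assert (mask <= once).all()
            np.testing.assert_array_equal(fill_holes(once), once)

    def test_matches_border_flood_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((16, 16)) < 0.5
            np.testing.assert_array_equal(fill_holes(mask), brute_fill_holes(mask))


class TestSieve:
    @staticmethod
    def _three_objects():
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[0:3, 0:4] = 1          # area 12
        labels[10:14, 10:15] = 2      # area 20
        labels[20:25, 20:29] = 3      # area 45
        return labels

    def test_greater_than_keeps_only_strictly_larger(self):
        out = sieve(self._three_objects(), SievePredicate("greater_than", 20))
        assert out.max() == 1
        assert (out == 1).sum() == 45  # boundary area 20 removed

    def test_less_than_keeps_only_strictly_smaller(self):
        out = sieve(self._three_objects(), SievePredicate("less_than", 20))
        assert out.max() == 1
        assert (out == 1).sum() == 12

    def test_empty_labelmap(self):
        out = sieve(np.zeros((5, 5), np.int32), SievePredicate("greater_than", 1))
        assert out.max() == 0

    def test_surviving_pixel_sets_unchanged(self, rng):
        from conftest import random_labels

        labels = random_labels(rng)
        out = sieve(labels, SievePredicate("greater_than", 10))
        np.testing.assert_array_equal(out, brute_sieve(labels, "greater_than", 10))


class TestBreakClumps:
    def test_two_discs_split_at_perpendicular_bisector(self):
        shape = (40, 60)
        mask = disc_mask(shape, 20, 24, 10) | disc_mask(shape, 20, 36, 10)
        seeds = np.zeros(shape, np.int32)
        seeds[20, 24], seeds[20, 36] = 1, 2
        out = break_clumps(mask, seeds)
        assert out.max() == 2
        ys, xs = np.nonzero(mask)
        for y, x in zip(ys, xs):
            if x <= 29:
                assert out[y, x] == 1
            elif x >= 31:
                assert out[y, x] == 2

    def test_single_seed_keeps_mask_whole(self):
        mask = disc_mask((30, 30), 15, 15, 8)
        seeds = np.zeros((30, 30), np.int32)
        seeds[14:17, 14:17] = 1
        out = break_clumps(mask, seeds)
        assert out.max() == 1
        np.testing.assert_array_equal(out > 0, mask)

    def test_random_blobs_match_exhaustive_nearest_seed(self, rng):
        for _ in range(20):
            mask = rng.random((24, 24)) < 0.45
            seeds = np.zeros((24, 24), np.int32)
            for lab in (1, 2, 3):
                ys, xs = np.nonzero(mask & (seeds == 0))
                if len(ys):
                    k = rng.integers(len(ys))
                    seeds[ys[k], xs[k]] = lab
            np.testing.assert_array_equal(
                break_clumps(mask, seeds), brute_break_clumps(mask, seeds)
            )

    def test_pixel_conserving(self, rng):
        mask = rng.random((32, 32)) < 0.4
        seeds = np.zeros((32, 32), np.int32)
        seeds[8, 8], seeds[20, 22] = 1, 2
        out = break_clumps(mask, seeds)
        np.testing.assert_array_equal(out > 0, mask)

    def test_equal_distance_property_exhaustive(self):
        """Each pixel's assigned seed is at minimal Euclidean distance."""
        mask = disc_mask((25, 25), 12, 10, 8) | disc_mask((25, 25), 12, 16, 8)
        seeds = np.zeros((25, 25), np.int32)
        seeds[12, 8], seeds[10, 17] = 1, 2
        out = break_clumps(mask, seeds)
        sy = {lab: np.argwhere(seeds == lab) for lab in (1, 2)}
        for y, x in np.argwhere(mask):
            assigned = out[y, x]
            d_assigned = min(((y - p) ** 2 + (x - q) ** 2) for p, q in sy[assigned])
            for other in (1, 2):
                d_other = min(((y - p) ** 2 + (x - q) ** 2) for p, q in sy[other])
                assert d_assigned <= d_other

    def test_seedless_component_gets_fresh_label(self):
        mask = disc_mask((40, 40), 10, 10, 5) | disc_mask((40, 40), 30, 30, 5)
        seeds = np.zeros((40, 40), np.int32)
        seeds[10, 10] = 1
        out = break_clumps(mask, seeds)
        assert out.max() == 2
        assert len(np.unique(out[disc_mask((40, 40), 30, 30, 5)])) == 1


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_fill_then_erode_stays_within_fill(seed):
    """Composition sanity: erosion of the filled mask never exceeds the fill."""
    rng = np.random.default_rng(seed)
    mask = rng.random((16, 16)) < 0.5
    filled = fill_holes(mask)
    assert (erode(filled, StructuringElement("disc", 3)) <= filled).all()
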