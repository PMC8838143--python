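import itertools

import numpy as np
import pytest

from lcnet.dataio import ImageRecord, Label
from lcnet.dedupe import GrayPair, deduplicate, image_correlation, to_grayscale


def _rand_rgb(rng, h=16, w=16):
    return rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)


class TestGrayscale:
    @pytest.mark.parametrize(
        "color,expected",
        [((255, 255, 255), 255.0), ((0, 0, 0), 0.0), ((255, 0, 0), 76.245)],
    )
    def test_luma_values(self, color, expected):
        img = np.tile(np.array(color, dtype=np.uint8), (4, 4, 1))
        assert to_grayscale(img) == pytest.approx(np.full((4, 4), expected))

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4)))


class TestCorrelation:
    def test_identical_is_one(self, rng):
        a = to_grayscale(_rand_rgb(rng))
        assert image_correlation(GrayPair(a, a.copy())) == pytest.approx(1.0)

    def test_inverted_is_minus_one(self, rng):
        a = to_grayscale(_rand_rgb(rng))
        assert image_correlation(GrayPair(a, 255.0 - a)) == pytest.approx(-1.0)

    def test_orthogonal_centered_patterns(self):
        a = np.array([[0.0, 0.0], [10.0, 10.0]])
        b = np.array([[0.0, 10.0], [0.0, 10.0]])
        assert image_correlation(GrayPair(a, b)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(20):
            a = to_grayscale(_rand_rgb(rng))
            b = to_grayscale(_rand_rgb(rng))
            assert image_correlation(GrayPair(a, b)) == pytest.approx(
                image_correlation(GrayPair(b, a)), abs=1e-12
            )

    def test_affine_intensity_invariance(self, rng):
        for alpha, beta in [(0.5, 10.0), (2.0, -3.0), (1.3, 0.0)]:
            a = to_grayscale(_rand_rgb(rng))
            assert image_correlation(GrayPair(a, alpha * a + beta)) == pytest.approx(1.0)

    def test_constant_image_is_zero_with_warning(self):
        a = np.full((4, 4), 7.0)
        b = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.warns(RuntimeWarning, match="constant"):
            assert image_correlation(GrayPair(a, b)) == 0.0

    def test_matches_pearson_oracle(self, rng):
        """Image-mode correlation is exactly Pearson on the flattened grids."""
        for _ in range(20):
            a = to_grayscale(_rand_rgb(rng))
            b = to_grayscale(_rand_rgb(rng))
            oracle = np.corrcoef(a.ravel(), b.ravel())[0, 1]
            assert image_correlation(GrayPair(a, b)) == pytest.approx(oracle, abs=1e-12)

    def test_histogram_mode_differs_from_image_mode(self, rng):
        a = to_grayscale(_rand_rgb(rng))
        b = np.rot90(a).copy()  # same histogram, different layout
        assert image_correlation(GrayPair(a, b), mode="histogram") == pytest.approx(1.0)
        assert image_correlation(GrayPair(a, b)) < 0.99

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            GrayPair(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_histogram_bins_sum_to_pixels(self, rng):
        a = to_grayscale(_rand_rgb(rng, 8, 8))
        pair = GrayPair(a, a)
        assert pair.hist_a.sum() == 64
        assert len(pair.hist_a) == 256


class TestDeduplicate:
    def _records(self, rng):
        a = _rand_rgb(rng, 32, 32)
        b = _rand_rgb(rng, 32, 32)
        return a, b

    def test_copy_removed_first_kept(self, rng):
        a, b = self._records(rng)
        recs = [
            ImageRecord("A", a, Label.MEL),
            ImageRecord("A2", a.copy(), Label.MEL),
            ImageRecord("B", b, Label.BEN),
        ]
        rep = deduplicate(recs)
        assert rep.kept == ["A", "B"]
        assert rep.removed == [("A2", "A", pytest.approx(1.0))]

    def test_threshold_is_strict(self, rng):
        a, b = self._records(rng)
        recs = [ImageRecord("A", a, Label.MEL), ImageRecord("B", b, Label.BEN)]
        # force threshold to exactly the observed correlation: strict > keeps both
        from lcnet.dedupe import CORRELATION_SIZE, _aligned_gray

        corr = image_correlation(
            GrayPair(_aligned_gray(recs[0], CORRELATION_SIZE), _aligned_gray(recs[1], CORRELATION_SIZE))
        )
        if 0 < corr <= 1:
            rep = deduplicate(recs, threshold=corr)
            assert rep.kept == ["A", "B"]

    def test_three_identical_point_at_first(self, rng):
        a, _ = self._records(rng)
        recs = [ImageRecord(f"A{i}", a.copy(), Label.MEL) for i in range(3)]
        rep = deduplicate(recs)
        assert rep.kept == ["A0"]
        assert [(r[0], r[1]) for r in rep.removed] == [("A1", "A0"), ("A2", "A0")]

    def test_empty_input(self):
        rep = deduplicate([])
        assert rep.kept == [] and rep.removed == []

    def test_idempotent(self, small_synth_set):
        records, _ = small_synth_set
        rep = deduplicate(records)
        kept = [r for r in records if r.id in set(rep.kept)]
        assert deduplicate(kept).removed == []

    def test_agrees_with_brute_force_oracle(self, rng):
        """Greedy scan agrees with all-pairs Pearson on flattened grids."""
        recs = [
            ImageRecord(f"r{i}", _rand_rgb(rng, 16, 16), Label.BEN) for i in range(10)
        ]
        recs.insert(5, ImageRecord("dup", recs[2].pixels.copy(), Label.BEN))
        rep = deduplicate(recs)
        grays = {r.id: to_grayscale(r.pixels).ravel() for r in recs}
        expected_removed = set()
        kept: list[str] = []
        for r in recs:
            hit = any(
                np.corrcoef(grays[r.id], grays[k])[0, 1] > 0.99 for k in kept
            )
            (expected_removed.add(r.id) if hit else kept.append(r.id))
        assert set(x[0] for x in rep.removed) == expected_removed == {"dup"}
        assert rep.kept == kept

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            deduplicate([], threshold=0.0)
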