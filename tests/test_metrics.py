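"""Image quality metrics and multi-objective indicators."""

import itertools

import numpy as np
import pytest

from gcfuse.metrics import (
    entropy,
    fmi,
    hypervolume,
    igd,
    metric_report,
    mutual_information,
    qabf,
    ssim,
)


def uniform_levels_image():
    """64x64 image hitting all 256 quantisation levels equally often."""
    vals = np.repeat(np.arange(256), 16) / 255.0
    return vals.reshape(64, 64)


class TestEntropy:
    def test_constant_zero(self):
        assert entropy(np.full((16, 16), 0.5)) == 0.0

    def test_two_equal_levels_one_bit(self):
        img = np.zeros((4, 4))
        img[:2] = 1.0
        assert entropy(img) == pytest.approx(1.0)

    def test_uniform_256_levels_eight_bits(self):
        assert entropy(uniform_levels_image()) == pytest.approx(8.0)

    def test_bounds(self, rng):
        e = entropy(rng.uniform(size=(32, 32)))
        assert 0.0 <= e <= 8.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.empty((0, 0)))


class TestMutualInformation:
    def test_self_information(self, rng):
        x = rng.uniform(size=(48, 48))
        assert mutual_information(x, x) == pytest.approx(entropy(x))

    def test_symmetry(self, rng):
        a, b = rng.uniform(size=(2, 32, 32))
        assert mutual_information(a, b) == pytest.approx(mutual_information(b, a))

    def test_independent_images_near_zero(self, rng):
        # binary-valued independent images: estimation bias stays tiny
        a = (rng.uniform(size=(256, 256)) > 0.5).astype(float)
        b = (rng.uniform(size=(256, 256)) > 0.5).astype(float)
        assert mutual_information(a, b) < 0.05

    def test_bounded_by_marginal_entropies(self, rng):
        a, b = rng.uniform(size=(2, 32, 32))
        mi = mutual_information(a, b)
        assert 0 <= mi <= min(entropy(a), entropy(b)) + 1e-12


class TestFMI:
    def test_self_fusion_is_one(self, phantom_small):
        ct = phantom_small.ct
        assert fmi(ct, ct, ct) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        f = rng.uniform(size=(128, 128))
        s1 = rng.uniform(size=(128, 128))
        s2 = rng.uniform(size=(128, 128))
        assert fmi(f, s1, s2) < 0.1

    def test_range_and_source_swap(self, rng):
        f, s1, s2 = rng.uniform(size=(3, 32, 32))
        v = fmi(f, s1, s2)
        assert 0.0 <= v <= 1.0
        assert fmi(f, s2, s1) == pytest.approx(v)

    def test_constant_images_defined_zero(self):
        c = np.full((16, 16), 0.5)
        assert fmi(c, c, c) == 0.0


class TestQabf:
    def test_self_fusion_near_perfect(self, phantom_small):
        ct = phantom_small.ct
        assert qabf(ct, ct, ct) >= 0.99

    def test_constant_fused_textured_sources(self, phantom_small):
        flat = np.full_like(phantom_small.ct, 0.5)
        assert qabf(flat, phantom_small.ct, phantom_small.mr) < 0.05

    def test_range_on_random_triples(self, rng):
        for _ in range(10):
            f, s1, s2 = rng.uniform(size=(3, 24, 24))
            assert 0.0 <= qabf(f, s1, s2) <= 1.0

    def test_all_flat_defined_zero(self):
        c = np.full((16, 16), 0.2)
        assert qabf(c, c, c) == 0.0


class TestSSIM:
    def test_identity(self, rng):
        x = rng.uniform(size=(32, 32))
        assert ssim(x, x) == 1.0

    def test_inverted_binary_negative(self):
        img = np.zeros((32, 32))
        img[:, ::2] = 1.0
        assert ssim(img, 1.0 - img) < 0.0

    def test_noise_monotonically_degrades(self, phantom_small):
        clean = phantom_small.mr
        rng = np.random.default_rng(0)
        vals = []
        for sigma in (0.02, 0.08, 0.2):
            noisy = np.clip(clean + rng.normal(0, sigma, clean.shape), 0, 1)
            vals.append(ssim(noisy, clean))
        assert vals[0] > vals[1] > vals[2]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((16, 16)), np.zeros((16, 17)))


class TestMetricReport:
    def test_keys_and_self_fusion_values(self, phantom_small):
        ct = phantom_small.ct
        rep = metric_report(ct, ct, ct)
        assert set(rep) == {"ENT", "MI", "FMI", "Qabf", "SSIM1", "SSIM2"}
        assert rep["SSIM1"] == 1.0 and rep["SSIM2"] == 1.0
        assert rep["MI"] == pytest.approx(entropy(ct))


class TestIGD:
    def test_identical_sets_zero(self, rng):
        p = rng.uniform(size=(20, 2))
        assert igd(p, p) == 0.0

    def test_hand_value(self):
        assert igd(np.array([[0.0, 0.0]]), np.array([[0, 1], [1, 0]])) == 1.0

    def test_superset_never_increases(self, rng):
        ref = rng.uniform(size=(30, 2))
        a = rng.uniform(size=(10, 2))
        base = igd(a, ref)
        assert igd(np.vstack([a, ref[:1]]), ref) <= base

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            igd(np.empty((0, 2)), np.ones((3, 2)))


def hv_monte_carlo(points, ref, n=1_000_000, seed=0):
    rng = np.random.default_rng(seed)
    lo = points.min(axis=0)
    samples = rng.uniform(lo, ref, size=(n, ref.shape[0]))
    dominated = np.zeros(n, dtype=bool)
    for p in points:
        dominated |= np.all(samples >= p, axis=1)
    box = np.prod(ref - lo)
    return box * dominated.mean()


def hv_inclusion_exclusion(points, ref):
    pts = points[np.all(points < ref, axis=1)]
    hv = 0.0
    for size in range(1, len(pts) + 1):
        for combo in itertools.combinations(range(len(pts)), size):
            corner = pts[list(combo)].max(axis=0)
            hv += (-1.0) ** (size + 1) * np.prod(np.maximum(ref - corner, 0))
    return hv


class TestHypervolume:
    def test_unit_rectangle(self):
        assert hypervolume(np.array([[1.0, 1.0]]), np.array([2.0, 2.0])) == 1.0

    def test_two_point_front(self):
        assert hypervolume(np.array([[0, 1], [1, 0]], float), np.array([2.0, 2.0])) == 3.0

    def test_sweep_matches_inclusion_exclusion_exactly(self, rng):
        for _ in range(20):
            pts = rng.uniform(size=(8, 2))
            ref = np.array([1.5, 1.5])
            assert hypervolume(pts, ref) == pytest.approx(
                hv_inclusion_exclusion(pts, ref), abs=1e-12
            )

    def test_points_outside_reference_ignored(self):
        pts = np.array([[1.0, 1.0], [3.0, 0.5]])
        assert hypervolume(pts, np.array([2.0, 2.0])) == hypervolume(
            pts[:1], np.array([2.0, 2.0])
        )

    def test_no_dominating_point_zero(self):
        assert hypervolume(np.array([[3.0, 3.0]]), np.array([2.0, 2.0])) == 0.0

    def test_monotone_under_added_point(self, rng):
        pts = rng.uniform(size=(6, 2))
        ref = np.array([2.0, 2.0])
        more = np.vstack([pts, rng.uniform(size=(1, 2))])
        assert hypervolume(more, ref) >= hypervolume(pts, ref) - 1e-12

    def test_translation_invariance(self, rng):
        pts = rng.uniform(size=(6, 2))
        ref = np.array([2.0, 2.0])
        shift = np.array([0.7, -0.3])
        assert hypervolume(pts + shift, ref + shift) == pytest.approx(
            hypervolume(pts, ref)
        )

    def test_three_objectives_inclusion_exclusion(self):
        pts = np.array([[1.0, 1.0, 1.0]])
        assert hypervolume(pts, np.array([2.0, 2.0, 2.0])) == 1.0
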