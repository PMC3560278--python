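"""Pseudo-Zernike moments: radial polynomials, invariances, Fisher selection."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from colonyscatter import (
    DiskMapping,
    FeatureVector,
    compute_pzm,
    extract_features,
    fisher_scores,
    map_to_disk,
    pzm_radial,
    select_features,
)


def oracle_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Independent radial polynomial via exact rational arithmetic."""
    total = np.zeros_like(np.asarray(rho, dtype=float))
    for s in range(n - abs(m) + 1):
        c = Fraction(
            (-1) ** s * factorial(2 * n + 1 - s),
            factorial(s) * factorial(n - abs(m) - s) * factorial(n + abs(m) + 1 - s),
        )
        total = total + float(c) * np.asarray(rho, float) ** (n - s)
    return total


def oracle_moments(img: np.ndarray, n_max: int) -> dict:
    """Brute-force moment computation: one explicit sum per (n, m)."""
    disk = map_to_disk(img, log_compress=False)
    out = {}
    for n in range(n_max + 1):
        for m in range(n + 1):
            R = oracle_radial(n, m, disk.rho)
            out[(n, m)] = (
                (n + 1) / np.pi
                * np.sum(disk.values * R * np.exp(-1j * m * disk.theta))
                * disk.delta_area
            )
    return out


class TestRadialPolynomial:
    def test_lowest_orders_closed_form(self):
        rho = np.linspace(0.0, 1.0, 11)
        np.testing.assert_allclose(pzm_radial(0, 0, rho), 1.0)
        np.testing.assert_allclose(pzm_radial(1, 1, rho), rho)
        np.testing.assert_allclose(pzm_radial(1, 0, rho), 3.0 * rho - 2.0)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_diagonal_is_monomial(self, n):
        """R(n, n, rho) reduces to the single s = 0 term, a multiple of rho^n."""
        rho = np.linspace(0.0, 1.0, 7)
        c = factorial(2 * n + 1) / (factorial(n) * 0 + factorial(2 * n + 1))
        np.testing.assert_allclose(pzm_radial(n, n, rho), c * rho**n)

    @pytest.mark.parametrize("n,np_,m", [(1, 3, 0), (2, 4, 1), (3, 5, 2), (2, 6, 0)])
    def test_orthogonality_with_weight_rho(self, n, np_, m):
        """int_0^1 R(n,m) R(n',m) rho drho = 0 for n != n'."""
        val, _ = quad(
            lambda r: pzm_radial(n, m, r) * pzm_radial(np_, m, r) * r, 0.0, 1.0
        )
        assert abs(val) < 1e-8

    def test_matches_rational_oracle(self):
        rho = np.linspace(0.0, 1.0, 9)
        for n in range(9):
            for m in range(n + 1):
                np.testing.assert_allclose(
                    pzm_radial(n, m, rho), oracle_radial(n, m, rho), rtol=1e-10
                )

    def test_invalid_repetition(self):
        with pytest.raises(ValueError):
            pzm_radial(2, 3, 0.5)


class TestDiskMapping:
    def test_uniform_image_maps_to_ones(self):
        disk = map_to_disk(np.ones((32, 32)), log_compress=False)
        np.testing.assert_array_equal(disk.values, 1.0)

    def test_center_pixel_has_zero_radius(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        disk = map_to_disk(img, log_compress=False)
        assert disk.rho.min() == 0.0
        assert disk.values[np.argmin(disk.rho)] == 1.0

    def test_off_center_mass_matches_pixel_sum(self, rng):
        """In-disk mass of an off-center mapping recomputes by direct pixel
        arithmetic from the radius/center geometry."""
        img = rng.uniform(size=(41, 41))
        mapping = DiskMapping(center=(15.0, 22.0), radius=10.0)
        disk = map_to_disk(img, mapping, log_compress=False)
        rows, cols = np.indices(img.shape)
        inside = np.hypot(rows - 15.0, cols - 22.0) <= 10.0
        assert disk.values.size == inside.sum()
        expected = img[inside].sum() / img[inside].max()
        np.testing.assert_allclose(disk.values.sum(), expected)

    def test_disk_outside_image_rejected(self):
        with pytest.raises(ValueError):
            map_to_disk(np.ones((16, 16)), DiskMapping(center=(2.0, 2.0), radius=10.0))

    def test_unit_integral_normalization(self, rng):
        img = rng.uniform(0.5, 1.5, size=(33, 33))
        disk = map_to_disk(img, DiskMapping(normalization="unit-integral"), log_compress=False)
        np.testing.assert_allclose(disk.values.sum() * disk.delta_area, 1.0)


class TestComputePZM:
    def test_uniform_disk_unit_zeroth_moment(self):
        """|A(0,0)| = 1 for the uniform unit image (A(0,0) = area/pi)."""
        disk = map_to_disk(np.ones((256, 256)), log_compress=False)
        pzm = compute_pzm(disk, 0)
        assert abs(pzm.magnitudes[0] - 1.0) < 1e-3

    def test_matches_brute_force_oracle(self, rng):
        img = rng.uniform(size=(64, 64))
        pzm = compute_pzm(map_to_disk(img, log_compress=False), 6)
        oracle = oracle_moments(img, 6)
        for idx, nm in enumerate(pzm.nm_pairs):
            assert abs(pzm.moments[idx] - oracle[nm]) <= 1e-6 * max(abs(oracle[nm]), 1e-12)

    def test_rotation_invariance_of_magnitudes(self, rng):
        """90/180/270-degree rotations leave every |A(n,m)| within 1%."""
        img = rng.uniform(size=(65, 65))
        base = compute_pzm(map_to_disk(img, log_compress=False), 8).magnitudes
        floor = 1e-9 * base.max()
        for k in (1, 2, 3):
            rot = compute_pzm(
                map_to_disk(np.rot90(img, k), log_compress=False), 8
            ).magnitudes
            drift = np.abs(rot - base) / np.maximum(base, floor)
            assert drift.max() < 0.01

    @pytest.mark.parametrize("n_max", [0, 3, 6, 17])
    def test_feature_count_identity(self, n_max, rng):
        img = rng.uniform(size=(32, 32))
        pzm = compute_pzm(map_to_disk(img, log_compress=False), n_max)
        assert len(pzm.nm_pairs) == (n_max + 1) * (n_max + 2) // 2
        assert pzm.magnitudes.size == len(pzm.nm_pairs)
        assert (pzm.magnitudes >= 0).all()

    def test_empty_disk_rejected(self):
        disk = map_to_disk(np.ones((16, 16)), log_compress=False)
        disk.values = disk.values[:0]
        with pytest.raises(ValueError):
            compute_pzm(disk, 2)


class TestFisher:
    def _vectors(self, rows, label):
        return [
            FeatureVector(values=np.asarray(r, float),
                          feature_ids=[(i, 0) for i in range(len(r))], label=label)
            for r in rows
        ]

    def test_hand_example(self):
        """good {1,2,3} vs bad {4,5,6}: F = (2-5)^2 / (1+1) = 4.5."""
        ranking = fisher_scores(
            self._vectors([[1.0], [2.0], [3.0]], "good"),
            self._vectors([[4.0], [5.0], [6.0]], "bad"),
        )
        assert ranking.scores[0] == pytest.approx(4.5, abs=1e-9)

    def test_equal_means_score_zero(self):
        ranking = fisher_scores(
            self._vectors([[1.0, 0.0], [3.0, 1.0]], "good"),
            self._vectors([[2.0, 5.0], [2.0, 6.0]], "bad"),
        )
        assert ranking.scores[0] == pytest.approx(0.0)

    def test_degenerate_variance_dominates(self):
        """Zero within-class variance gives the finite ceiling 1/eps, which
        outranks every ordinary feature."""
        ranking = fisher_scores(
            self._vectors([[0.0, 1.0], [0.0, 2.0]], "good"),
            self._vectors([[1.0, 8.0], [1.0, 9.0]], "bad"),
        )
        assert np.isfinite(ranking.scores[0])
        assert ranking.scores[0] == pytest.approx(1e12)
        assert ranking.ranking[0] == 0

    def test_dimension_mismatch_and_small_class(self):
        with pytest.raises(ValueError):
            fisher_scores(np.ones((3, 4)), np.ones((3, 5)))
        with pytest.raises(ValueError):
            fisher_scores(np.ones((1, 4)), np.ones((3, 4)))

    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, shift, scale):
        """Joint translation leaves F unchanged; positive joint scaling
        leaves the ranking unchanged."""
        rng = np.random.default_rng(99)
        good = rng.normal(0.0, 1.0, (10, 5)) + np.arange(5)
        bad = rng.normal(0.5, 1.3, (10, 5))
        base = fisher_scores(good, bad)
        shifted = fisher_scores(good + shift, bad + shift)
        np.testing.assert_allclose(shifted.scores, base.scores, rtol=1e-8)
        scaled = fisher_scores(good * scale, bad * scale)
        np.testing.assert_array_equal(scaled.ranking, base.ranking)


class TestSelectFeatures:
    def _make(self, rng, n_features=12, n_each=5):
        good = [FeatureVector(rng.uniform(size=n_features),
                              [(i, 0) for i in range(n_features)], label="good")
                for _ in range(n_each)]
        bad = [FeatureVector(rng.uniform(size=n_features) + np.linspace(0, 1, n_features),
                             [(i, 0) for i in range(n_features)], label="bad")
               for _ in range(n_each)]
        return good, bad

    def test_selected_dimension(self, rng):
        good, bad = self._make(rng)
        ranking = fisher_scores(good, bad)
        out = select_features(ranking, good + bad, k=7)
        assert all(v.values.size == 7 for v in out)
        assert all(len(v.feature_ids) == 7 for v in out)

    def test_paper_scale_selection_from_default_order(self, rng):
        """n_max = 17 gives 171 magnitudes; the default selection keeps 161."""
        img = rng.uniform(size=(64, 64))
        fv = extract_features(img, n_max=17)
        assert fv.values.size == 171
        good = [FeatureVector(fv.values + rng.normal(0, 0.01, 171), fv.feature_ids, label="good")
                for _ in range(4)]
        bad = [FeatureVector(fv.values + 1 + rng.normal(0, 0.01, 171), fv.feature_ids, label="bad")
               for _ in range(4)]
        ranking = fisher_scores(good, bad)
        out = select_features(ranking, good + bad, k=161)
        assert out[0].values.size == 161

    def test_k_one_is_argmax(self, rng):
        good, bad = self._make(rng)
        ranking = fisher_scores(good, bad)
        out = select_features(ranking, good, k=1)
        assert out[0].feature_ids[0] == good[0].feature_ids[int(np.argmax(ranking.scores))]

    def test_k_total_is_score_ordering(self, rng):
        good, bad = self._make(rng)
        ranking = fisher_scores(good, bad)
        out = select_features(ranking, [good[0]], k=12)
        assert out[0].values.size == 12
        scores_in_order = ranking.scores[ranking.ranking]
        assert (np.diff(scores_in_order) <= 0).all()

    def test_k_too_large_rejected(self, rng):
        good, bad = self._make(rng)
        ranking = fisher_scores(good, bad)
        with pytest.raises(ValueError):
            select_features(ranking, good, k=13)
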