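"""Delay embedding, recurrence matrices against a brute-force oracle, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpaf.recurrence import (
    RpConfig,
    ecg_to_rp,
    render_rp_image,
    rp_matrix_from_segment,
    takens_embed,
    thresholded_rp,
    unthresholded_rp,
)
from rpaf.synthetic_ecg import generate_record


def brute_force_distances(points, norm="euclidean"):
    """O(N^2) naive oracle, independent of the library path."""
    n = len(points)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = points[i] - points[j]
            if norm == "euclidean":
                out[i, j] = np.sqrt(d @ d)
            elif norm == "max":
                out[i, j] = np.abs(d).max()
            else:
                out[i, j] = np.abs(d).sum()
    return out


class TestTakensEmbed:
    def test_worked_example(self):
        traj = takens_embed([1, 2, 3, 4], tau=1)
        assert np.array_equal(traj.points, [[2, 1], [3, 2], [4, 3]])

    def test_point_count(self, rng):
        x = rng.standard_normal(3000)
        assert len(takens_embed(x, tau=1)) == 2999
        assert len(takens_embed(x, tau=5)) == 2995

    def test_constant_series_collapses(self):
        traj = takens_embed(np.full(10, 2.0))
        assert np.all(traj.points == 2.0)

    def test_lag_relation(self, rng):
        x = rng.standard_normal(50)
        traj = takens_embed(x, tau=3)
        assert np.array_equal(traj.points[:, 0], x[3:])
        assert np.array_equal(traj.points[:, 1], x[:-3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            takens_embed([1.0], tau=1)


class TestRecurrenceMatrices:
    def test_3_4_5_triangle(self):
        traj = takens_embed([0, 0, 4, 3.0], tau=2)  # points (4,0), (3,0)... distances
        R = unthresholded_rp(traj)
        assert R.values.shape == (2, 2)
        assert R.values[0, 1] == R.values[1, 0] == 1.0

    def test_explicit_345(self):
        from rpaf.recurrence import Trajectory

        R = unthresholded_rp(Trajectory(points=np.array([[0.0, 0.0], [3.0, 4.0]])))
        assert np.array_equal(R.values, [[0, 5], [5, 0]])

    def test_identical_points_zero_matrix(self):
        traj = takens_embed(np.full(20, 1.5))
        assert np.all(unthresholded_rp(traj).values == 0)

    @pytest.mark.parametrize("norm", ["euclidean", "max", "manhattan"])
    def test_matches_brute_force_oracle(self, rng, norm):
        x = rng.standard_normal(52)
        traj = takens_embed(x)
        R = unthresholded_rp(traj, norm=norm)
        assert np.allclose(R.values, brute_force_distances(traj.points, norm), atol=1e-12)

    def test_symmetry_and_zero_diagonal(self, rng):
        traj = takens_embed(rng.standard_normal(100))
        R = unthresholded_rp(traj)
        assert np.array_equal(R.values, R.values.T)
        assert np.all(np.diag(R.values) == 0)

    def test_threshold_boundary_inclusive(self):
        """A pair at distance exactly epsilon recurs (Heaviside(0) = 1)."""
        from rpaf.recurrence import Trajectory

        traj = Trajectory(points=np.array([[0.0, 0.0], [3.0, 4.0]]))
        B = thresholded_rp(traj, epsilon=5.0)
        assert B.values[0, 1] == 1

    def test_threshold_extremes(self, rng):
        x = rng.standard_normal(30)
        traj = takens_embed(x)
        assert np.all(thresholded_rp(traj, 1e9).values == 1)
        eye = thresholded_rp(traj, 0.0).values
        assert np.array_equal(eye, np.eye(len(traj), dtype=np.uint8))

    def test_negative_epsilon_rejected(self, rng):
        with pytest.raises(ValueError):
            thresholded_rp(takens_embed(rng.standard_normal(10)), -0.1)

    @given(eps=st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=20, deadline=None)
    def test_threshold_equals_indicator_of_unthresholded(self, eps):
        rng = np.random.default_rng(17)
        traj = takens_embed(rng.standard_normal(40))
        U = unthresholded_rp(traj).values
        B = thresholded_rp(traj, eps).values
        assert np.array_equal(B, (U <= eps).astype(np.uint8))

    def test_order_sensitivity(self, rng):
        """Reversing the series changes the recurrence matrix layout but a
        symmetric permutation of indices maps one onto the other."""
        x = rng.standard_normal(30)
        R1 = unthresholded_rp(takens_embed(x)).values
        R2 = unthresholded_rp(takens_embed(x[::-1])).values
        assert not np.allclose(R1, R2)


class TestRendering:
    def test_shape_and_range(self, rng):
        R = unthresholded_rp(takens_embed(rng.standard_normal(50)))
        img = render_rp_image(R, size=299)
        assert img.pixels.shape == (299, 299, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_zero_matrix_uniform_image(self):
        R = unthresholded_rp(takens_embed(np.full(10, 3.0)))
        img = render_rp_image(R, size=16)
        assert np.allclose(img.pixels, img.pixels[0, 0])

    def test_scale_invariance(self, rng):
        from dataclasses import replace

        R = unthresholded_rp(takens_embed(rng.standard_normal(60)))
        R5 = replace(R, values=5.0 * R.values)
        a = render_rp_image(R, size=32)
        b = render_rp_image(R5, size=32)
        assert np.array_equal(a.pixels, b.pixels)

    def test_size_too_small(self, rng):
        R = unthresholded_rp(takens_embed(rng.standard_normal(10)))
        with pytest.raises(ValueError):
            render_rp_image(R, size=1)


class TestEcgToRp:
    def test_deterministic(self, synth_cfg, rp_small_cfg):
        rec = generate_record(synth_cfg, "AF", seed=6)
        a = ecg_to_rp(rec.lead("II"), rec.fs, rp_small_cfg)
        b = ecg_to_rp(rec.lead("II"), rec.fs, rp_small_cfg)
        assert np.array_equal(a.pixels, b.pixels)

    def test_decimation_matrix_side(self, synth_cfg):
        """A 10 s segment decimated to 300 samples embeds into a 299-sided
        matrix, rendered 1:1 at the native 299 input size."""
        rec = generate_record(synth_cfg, "NSR", seed=6)
        cfg = RpConfig(target_points=300, size=299)
        R = rp_matrix_from_segment(rec.lead("II"), cfg)
        assert R.values.shape == (299, 299)
        img = ecg_to_rp(rec.lead("II"), rec.fs, cfg)
        assert img.pixels.shape == (299, 299, 3)

    def test_nsr_texture_more_periodic_than_af(self, synth_cfg):
        """The row-mean profile of an NSR recurrence matrix is strongly
        autocorrelated at the RR lag (regular beat grid) while an AF one is
        not; compared pairwise over seeded record pairs."""
        from skimage.transform import resize_local_mean

        cfg = RpConfig(full_matrix=True)
        duration = 5.0

        def rr_lag_autocorr(x):
            R = rp_matrix_from_segment(x, cfg).values
            prof = resize_local_mean(R, (64, 64)).mean(axis=1)
            prof = prof - prof.mean()
            lag0 = synth_cfg.rr_mean_nsr / duration * len(prof)
            best = -1.0
            for lag in range(max(1, int(lag0 * 0.85)), int(lag0 * 1.15) + 1):
                den = np.sqrt(np.sum(prof[:-lag] ** 2) * np.sum(prof[lag:] ** 2))
                if den > 0:
                    best = max(best, float(np.sum(prof[:-lag] * prof[lag:]) / den))
            return best

        scores = {"AF": [], "NSR": []}
        for label in scores:
            for seed in range(25):
                rec = generate_record(synth_cfg, label, seed=seed)
                x = rec.lead("II")[: int(duration * synth_cfg.fs)]
                scores[label].append(rr_lag_autocorr(x))
        wins = np.mean([n > a for n, a in zip(scores["NSR"], scores["AF"])])
        assert np.mean(scores["NSR"]) > np.mean(scores["AF"])
        assert wins >= 0.8
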