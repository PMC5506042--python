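"""Spatial normalization: window partition, LTS fits, adjustment, summarization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualeigen import (
    ProbeChip,
    SubsubConfig,
    fit_piecewise_lts,
    generate_probe_chip,
    partition_subarrays,
    subsub_normalize,
    summarize_ptr,
)
from dualeigen.preprocess import _design, median_polish


def brute_force_lts(x, y, config):
    """Independent oracle: exhaustive best-h-subset LTS via per-subset lstsq.

    Same model family as the implementation: the one-knot fit applies when
    the subset has >= 3 points on each side of the knot, else a single line.
    """
    import math

    n = len(x)
    h = math.ceil(config.lts_coverage_fraction * n)
    lo, hi = x.min(), x.max()
    knots = [float(k) for k in np.unique(np.quantile(x, config.knot_quantiles))
             if lo < k < hi]
    best = None
    for knot in knots:
        X = _design(x, knot)
        for subset in itertools.combinations(range(n), h):
            idx = list(subset)
            below = int((x[idx] < knot).sum())
            Xs = X[idx] if min(below, h - below) >= 3 else X[idx][:, :2]
            beta, *_ = np.linalg.lstsq(Xs, y[idx], rcond=None)
            rss = float(((y[idx] - Xs @ beta) ** 2).sum())
            if best is None or rss < best[0] - 1e-10 * (1.0 + best[0]):
                if len(beta) == 2:
                    beta = np.array([beta[0], beta[1], 0.0])
                best = (rss, knot, beta)
    return best


class TestPartition:
    def test_100_grid_defaults(self):
        wins = partition_subarrays(100, 100, SubsubConfig())
        starts = sorted({w[0] for w in wins})
        assert starts == [0, 25, 50]
        assert len(wins) == 9

    def test_1002_grid_defaults_edge_anchored(self):
        wins = partition_subarrays(1002, 1002, SubsubConfig())
        starts = sorted({w[0] for w in wins})
        assert starts == list(range(0, 951, 25)) + [952]
        assert len(starts) == 40
        assert len(wins) == 1600

    def test_exact_fit_single_window(self):
        assert partition_subarrays(50, 50, SubsubConfig()) == [(0, 0, 50)]

    def test_overlap_must_be_smaller_than_size(self):
        with pytest.raises(ValueError):
            partition_subarrays(100, 100, SubsubConfig(subarray_size=50, overlap=50))

    @given(rows=st.integers(50, 400), cols=st.integers(50, 400))
    @settings(max_examples=25, deadline=None)
    def test_coverage_bounds(self, rows, cols):
        """Every cell in >= 1 window; <= 2 regular windows per axis, so <= 4
        away from edges and <= 9 where an edge-anchored window overlaps."""
        config = SubsubConfig()
        counts = np.zeros((rows, cols))
        for r0, c0, size in partition_subarrays(rows, cols, config):
            counts[r0: r0 + size, c0: c0 + size] += 1
        assert counts.min() >= 1
        assert counts.max() <= 9
        # without an edge-anchored window the regular bound is 2 per axis
        if (rows - 50) % 25 == 0 and (cols - 50) % 25 == 0:
            assert counts.max() <= 4


class TestPiecewiseLTS:
    def test_identity_data_gives_identity_fit(self):
        x = np.linspace(0, 10, 30)
        fit = fit_piecewise_lts(x, x)
        assert fit.left_slope == pytest.approx(1.0, abs=1e-9)
        assert fit.right_slope == pytest.approx(1.0, abs=1e-9)
        assert fit.left_intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.trimmed_rss == pytest.approx(0.0, abs=1e-16)

    def test_constant_shift_recovered(self):
        x = np.linspace(0, 10, 30)
        fit = fit_piecewise_lts(x, x + 3.0)
        assert fit.left_slope == pytest.approx(1.0, abs=1e-9)
        assert fit.right_slope == pytest.approx(1.0, abs=1e-9)
        assert fit.left_intercept == pytest.approx(3.0, abs=1e-8)

    def test_gross_outliers_ignored(self, rng):
        x = rng.uniform(0, 10, 20)
        y = 2.0 * x
        y[:4] += 9.0  # 20% gross contamination, below 25% breakdown
        fit = fit_piecewise_lts(x, y)
        assert fit.left_slope == pytest.approx(2.0, abs=1e-6)
        assert fit.right_slope == pytest.approx(2.0, abs=1e-6)

    def test_matches_brute_force_oracle_small_n(self, rng):
        config = SubsubConfig()
        for _ in range(5):
            n = int(rng.integers(8, 13))
            x = rng.uniform(0, 10, n)
            y = 1.5 * x - 2 + rng.normal(0, 0.3, n)
            fit = fit_piecewise_lts(x, y, config)
            rss, knot, beta = brute_force_lts(x, y, config)
            assert fit.trimmed_rss == pytest.approx(rss, rel=1e-9, abs=1e-12)
            assert fit.knot == pytest.approx(knot)

    def test_constant_x_falls_back_flagged(self):
        x = np.full(10, 5.0)
        y = np.r_[np.ones(8), 9.0, 9.0]
        fit = fit_piecewise_lts(x, y)
        assert fit.degenerate
        assert fit.predict(np.array([5.0]))[0] == pytest.approx(1.0)

    def test_continuity_at_knot(self, rng):
        x = rng.uniform(0, 10, 40)
        y = np.where(x < 5, x, 5 + 2 * (x - 5)) + rng.normal(0, 0.1, 40)
        fit = fit_piecewise_lts(x, y)
        eps = 1e-9
        left = fit.left_intercept + fit.left_slope * (fit.knot - eps)
        right = fit.right_intercept + fit.right_slope * (fit.knot + eps)
        assert left == pytest.approx(right, abs=1e-6)


class TestSubsubNormalize:
    def test_self_normalization_is_exact_identity(self):
        pair = generate_probe_chip(side=120, artifact="blotch", seed=9)
        out = subsub_normalize(pair.target, pair.target)
        assert np.array_equal(out.values, pair.target.values)

    def test_global_constant_shift_absorbed_exactly(self):
        pair = generate_probe_chip(side=100, artifact="none", seed=2, noise_sd=0.0)
        target = ProbeChip(pair.reference.values + 2.0, pair.reference.probeset_map)
        out = subsub_normalize(target, pair.reference)
        assert np.allclose(out.values, pair.reference.values, atol=1e-7)

    def test_regional_constant_shift_absorbed_in_homogeneous_windows(self):
        pair = generate_probe_chip(side=100, artifact="none", seed=2, noise_sd=0.0)
        target_vals = pair.reference.values.copy()
        target_vals[50:, 50:] += 2.0  # shift aligned with the window grid
        target = ProbeChip(target_vals, pair.reference.probeset_map)
        out = subsub_normalize(target, pair.reference)
        # cells covered only by fully-shifted or fully-unshifted windows recover
        assert np.allclose(out.values[:25, :25], pair.reference.values[:25, :25], atol=1e-7)
        assert np.allclose(out.values[75:, 75:], pair.reference.values[75:, 75:], atol=1e-7)
        # and the artifact shrinks overall
        before = np.abs(target.values - pair.reference.values).mean()
        after = np.abs(out.values - pair.reference.values).mean()
        assert after < 0.5 * before  # mixed windows retain part of the artifact

    def test_gradient_artifact_reduced_in_every_window(self):
        pair = generate_probe_chip(side=150, artifact="gradient", seed=3)
        out = subsub_normalize(pair.target, pair.reference)
        config = SubsubConfig()
        for r0, c0, size in partition_subarrays(150, 150, config):
            sl = (slice(r0, r0 + size), slice(c0, c0 + size))
            before = np.abs(pair.target.values[sl] - pair.reference.values[sl]).mean()
            after = np.abs(out.values[sl] - pair.reference.values[sl]).mean()
            assert after < before

    def test_geometry_mismatch_rejected(self):
        a = generate_probe_chip(side=60, artifact="none", seed=0).reference
        b = generate_probe_chip(side=80, artifact="none", seed=0).reference
        with pytest.raises(ValueError, match="geometr"):
            subsub_normalize(a, b)


class TestSummarizePTR:
    @staticmethod
    def _chips_from_stack(stack, n_probes, probes_per_set):
        """Build single-row chips from a (probes, chips) value matrix."""
        n_sets = n_probes // probes_per_set
        ids = np.repeat([f"s{i}" for i in range(n_sets)], probes_per_set)
        pmap = np.array(ids, dtype="U8").reshape(1, -1)
        return {
            f"chip{j}": ProbeChip(stack[:, j].reshape(1, -1), pmap)
            for j in range(stack.shape[1])
        }

    def test_exact_additive_model_recovered(self):
        alpha = np.array([-1.0, 0.5, 0.2, 0.3, 0.0, 0.0, 0.0, -0.2, 0.1, 0.05, 0.05])
        beta = np.array([0.0, 1.0, -0.5, 2.0])
        stack = 7.0 + alpha[:, None] + beta[None, :]
        chips = self._chips_from_stack(stack, 11, 11)
        result = summarize_ptr(chips, references=["chip0"])
        vals = result.profile.values.loc["s0"]
        # probe effects are median-constrained, so chip-effect *differences*
        # are the identifiable quantities and are recovered exactly
        assert vals["chip1"] - vals["chip2"] == pytest.approx(1.5, abs=1e-10)
        assert vals["chip3"] - vals["chip1"] == pytest.approx(1.0, abs=1e-10)

    def test_probe_bias_on_all_chips_absorbed(self):
        alpha = np.zeros(11)
        beta = np.array([0.0, 1.0, -0.5, 2.0])
        clean = 7.0 + alpha[:, None] + beta[None, :]
        biased = clean.copy()
        biased[4, :] += 5.0  # one probe systematically off on every chip
        res_clean = summarize_ptr(self._chips_from_stack(clean, 11, 11), ["chip0"])
        res_biased = summarize_ptr(self._chips_from_stack(biased, 11, 11), ["chip0"])
        assert np.allclose(
            res_clean.profile.values.to_numpy(),
            res_biased.profile.values.to_numpy(),
            atol=1e-10,
        )

    def test_single_chip_outlier_damped_relative_to_mean(self):
        clean = np.full((11, 4), 7.0)
        corrupted = clean.copy()
        corrupted[4, 2] += 5.0  # one probe, one chip
        res = summarize_ptr(self._chips_from_stack(corrupted, 11, 11), ["chip0"])
        deviation = abs(res.profile.values.loc["s0", "chip2"] - 7.0)
        assert deviation < 5.0 / 11.0  # naive mean would deviate by exactly 5/11

    def test_small_probeset_falls_back_to_mean_flagged(self):
        pmap = np.array([["a", "b", "b", "b"]])
        chips = {
            "ref": ProbeChip(np.array([[1.0, 2.0, 2.0, 2.0]]), pmap),
            "t": ProbeChip(np.array([[3.0, 4.0, 4.0, 4.0]]), pmap),
        }
        res = summarize_ptr(chips, references=["ref"])
        assert res.flagged_probesets == ["a"]
        assert res.profile.values.loc["a", "t"] == pytest.approx(3.0)

    def test_requires_reference(self):
        pair = generate_probe_chip(side=60, artifact="none", seed=1)
        with pytest.raises(ValueError):
            summarize_ptr({"a": pair.reference}, references=[])


class TestMedianPolish:
    def test_exact_additive_decomposition(self):
        row = np.array([1.0, -1.0, 0.0])
        col = np.array([2.0, 0.0, -2.0, 0.0])
        mat = 5.0 + row[:, None] + col[None, :]
        overall, r, c, resid = median_polish(mat)
        assert overall + c[0] == pytest.approx(7.0)
        assert np.allclose(resid, 0.0, atol=1e-12)
        assert np.median(r) == pytest.approx(0.0, abs=1e-12)
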