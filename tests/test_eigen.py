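"""SVD core: decomposition quality, contribution convention, sign anchoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualeigen import (
    ExpressionProfile,
    SimulationSpec,
    compute_svd,
    contribution_percentages,
    fix_signs,
    generate_profile,
)


def _profile_from_matrix(m, rng=None):
    g, s = m.shape
    values = pd.DataFrame(
        m,
        index=[f"g{i}" for i in range(g)],
        columns=[f"smp{j}" for j in range(s)],
    )
    return ExpressionProfile(values)


class TestComputeSVD:
    def test_rank_one_matrix(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=5)
        dec = compute_svd(_profile_from_matrix(np.outer(a, b)), centering="none")
        assert dec.rho[0] == pytest.approx(np.linalg.norm(a) * np.linalg.norm(b))
        assert np.all(dec.rho[1:] < 1e-10 * dec.rho[0])

    def test_reconstruction_and_gram_matrix_oracle(self, rng):
        m = rng.normal(size=(5, 4))
        dec = compute_svd(_profile_from_matrix(m), centering="none")
        assert np.allclose(dec.reconstruct(), m, atol=1e-10)
        # independent route: eigendecomposition of the sample Gram matrix
        evals, evecs = np.linalg.eigh(m.T @ m)
        order = np.argsort(evals)[::-1]
        assert np.allclose(np.sqrt(np.maximum(evals[order], 0)), dec.rho, atol=1e-10)
        for k in range(4):
            assert abs(evecs[:, order[k]] @ dec.v[:, k]) == pytest.approx(1.0, abs=1e-8)

    def test_orthonormality(self, default_decompositions):
        pooled, control = default_decompositions
        for dec in (pooled, control):
            k = dec.n_components
            assert np.allclose(dec.u.T @ dec.u, np.eye(k), atol=1e-8)
            assert np.allclose(dec.v.T @ dec.v, np.eye(k), atol=1e-8)

    def test_centered_reconstruction_tolerance(self, default_sim):
        profile, _ = default_sim
        dec = compute_svd(profile, centering="gene")
        m = profile.matrix()
        centered = m - m.mean(axis=1, keepdims=True)
        err = np.linalg.norm(dec.reconstruct() - centered) / np.linalg.norm(centered)
        assert err < 1e-6

    def test_column_permutation_symmetry(self, rng):
        m = rng.normal(size=(40, 6))
        perm = rng.permutation(6)
        d1 = compute_svd(_profile_from_matrix(m), centering="none")
        d2 = compute_svd(_profile_from_matrix(m[:, perm]), centering="none")
        assert np.allclose(d1.rho, d2.rho, atol=1e-10)
        for k in range(6):
            # same component up to sign: gene vectors match, sample loadings permute
            sign = np.sign(d1.u[:, k] @ d2.u[:, k])
            assert np.allclose(d1.u[:, k], sign * d2.u[:, k], atol=1e-8)
            assert np.allclose(d1.v[perm, k], sign * d2.v[:, k], atol=1e-8)

    def test_determinism(self, default_sim):
        profile, _ = default_sim
        d1 = compute_svd(profile)
        d2 = compute_svd(profile)
        assert np.array_equal(d1.u, d2.u) and np.array_equal(d1.rho, d2.rho)

    def test_missing_entries_refused(self):
        values = pd.DataFrame(
            [[1.0, np.nan], [0.0, 1.0]], index=["a", "b"], columns=["s1", "s2"]
        )
        with pytest.raises(ValueError, match="missing"):
            ExpressionProfile(values)


class TestContributionPercentages:
    def test_equal_values(self):
        assert np.allclose(
            contribution_percentages(np.ones(4)), [25.0, 50.0, 75.0, 100.0]
        )

    @pytest.mark.parametrize(
        "rho1, pct1, rho_rest, expected",
        [
            # printed top-3 singular values; total implied by the rank-1 percentage
            (1.482, 14.77, [1.244, 0.856], [27.17, 35.70]),   # pancreas
            (2.147, 16.06, [1.165, 1.070], [24.77, 32.77]),   # adipose
            (1.404, 11.46, [1.092, 0.990], [20.38, 28.45]),   # liver
        ],
    )
    def test_published_cumulative_percentages(self, rho1, pct1, rho_rest, expected):
        total = rho1 / (pct1 / 100.0)
        rho = np.array([rho1, *rho_rest])
        cum = 100.0 * np.cumsum(rho) / total  # same convention, explicit total
        assert cum[1] == pytest.approx(expected[0], abs=0.05)
        assert cum[2] == pytest.approx(expected[1], abs=0.05)
        # and contribution_percentages implements exactly this linear convention:
        # spread the unprinted tail over enough small values to keep rho sorted
        tail = total - rho.sum()
        n_tail = int(np.ceil(tail / rho[-1]))
        full = np.concatenate([rho, np.full(n_tail, tail / n_tail)])
        assert np.allclose(contribution_percentages(full)[:3], cum, atol=1e-9)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_invariance(self, scale):
        rho = np.array([4.0, 2.0, 1.0])
        assert np.allclose(
            contribution_percentages(rho), contribution_percentages(scale * rho)
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contribution_percentages(np.zeros(3))


class TestFixSigns:
    def test_already_anchored_is_identity(self, default_sim):
        profile, _ = default_sim
        dec = compute_svd(profile)
        anchored = fix_signs(dec, profile.attributes, "week")
        if not anchored.anchors[0]["flipped"]:
            assert np.array_equal(anchored.u[:, 0], dec.u[:, 0])
        twice = fix_signs(anchored, profile.attributes, "week")
        assert np.array_equal(twice.u, anchored.u)
        assert np.array_equal(twice.v, anchored.v)

    def test_reconstruction_invariant_under_anchoring(self, default_sim):
        profile, _ = default_sim
        dec = compute_svd(profile)
        anchored = fix_signs(dec, profile.attributes, "week")
        assert np.allclose(dec.reconstruct(), anchored.reconstruct(), atol=1e-12)
        assert np.array_equal(dec.rho, anchored.rho)

    @pytest.mark.parametrize("seed", range(10))
    def test_week_anchored_endogenous_loading_positive_correlation(self, seed):
        profile, truth = generate_profile(SimulationSpec(seed=seed))
        dec = fix_signs(compute_svd(profile), profile.attributes, "week")
        week = profile.attributes["week"].to_numpy(dtype=float)
        k = int(np.argmax(np.abs(dec.u.T @ truth.endo_u)))
        v = dec.v[:, k]
        assert np.corrcoef(v, week)[0, 1] > 0

    def test_degenerate_anchor_uses_largest_loading(self):
        values = pd.DataFrame(
            np.outer([3.0, -1.0, 0.5], [1.0, -2.0, 0.5, 1.5]),
            index=["a", "b", "c"],
            columns=["s1", "s2", "s3", "s4"],
        )
        attrs = pd.DataFrame({"week": [1, 1, 1, 1]}, index=values.columns)
        dec = compute_svd(ExpressionProfile(values, attrs), centering="none")
        anchored = fix_signs(dec, attrs, "week")
        assert anchored.anchors[0]["degenerate"]
        v = anchored.v[:, 0]
        assert v[np.argmax(np.abs(v))] > 0
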