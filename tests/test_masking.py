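import math

import numpy as np
import pytest

from maest import (
    MaskPlan,
    ReconLossConfig,
    draw_mask_plan,
    mask_features,
    reconstruction_loss,
    regularization_loss,
    remask_latent,
    scaled_cosine_error,
)
from maest.nn import ProjectorParams


def sce_oracle(x, z, gamma):
    """Independent scalar implementation of the scaled cosine error."""
    dot = sum(a * b for a, b in zip(x, z))
    nx = math.sqrt(sum(a * a for a in x))
    nz = math.sqrt(sum(b * b for b in z))
    return (1.0 - dot / (nx * nz)) ** gamma


def _plan(n, masked, k=1, remasks=None, rate=0.5):
    remasks = remasks if remasks is not None else [[] for _ in range(k)]
    return MaskPlan(rate, np.asarray(masked, dtype=int), k, [np.asarray(r, dtype=int) for r in remasks])


class TestMaskFeatures:
    def test_rate_zero_identity(self, rng):
        X = rng.normal(size=(6, 4)) ** 2
        plan = draw_mask_plan(6, 0.0, 1, rng)
        np.testing.assert_array_equal(mask_features(X, plan), X)

    def test_rate_one_all_zero(self, rng):
        X = rng.normal(size=(6, 4))
        plan = draw_mask_plan(6, 1.0, 1, rng)
        np.testing.assert_array_equal(mask_features(X, plan), np.zeros_like(X))

    def test_rate_point_three_masks_three_rows_reproducibly(self):
        X = np.ones((10, 3))
        plans = [
            draw_mask_plan(10, 0.3, 2, np.random.default_rng(7)) for _ in range(2)
        ]
        masked = [mask_features(X, p) for p in plans]
        assert int((masked[0] == 0).all(axis=1).sum()) == 3
        np.testing.assert_array_equal(plans[0].masked_nodes, plans[1].masked_nodes)
        np.testing.assert_array_equal(masked[0], masked[1])

    def test_unmasked_rows_bit_identical(self, rng):
        X = rng.normal(size=(8, 5))
        plan = _plan(8, [1, 4])
        out = mask_features(X, plan)
        np.testing.assert_array_equal(out[[0, 2, 3, 5, 6, 7]], X[[0, 2, 3, 5, 6, 7]])


class TestRemaskLatent:
    def test_empty_set_identity(self, rng):
        H = rng.normal(size=(5, 3))
        plan = _plan(5, [0], k=1, remasks=[[]])
        np.testing.assert_array_equal(remask_latent(H, plan, 1), H)

    def test_full_set_zeroes(self, rng):
        H = rng.normal(size=(5, 3))
        plan = _plan(5, [0], k=1, remasks=[list(range(5))])
        np.testing.assert_array_equal(remask_latent(H, plan, 1), np.zeros_like(H))

    def test_views_differ_with_high_probability(self):
        rng = np.random.default_rng(11)
        plan = draw_mask_plan(50, 0.5, 2, rng)
        assert set(plan.remask_sets[0]) != set(plan.remask_sets[1])

    def test_view_bounds_checked(self, rng):
        plan = _plan(5, [0], k=1, remasks=[[1]])
        with pytest.raises(ValueError, match="view"):
            remask_latent(rng.normal(size=(5, 2)), plan, 2)


class TestScaledCosineError:
    def test_identical_vectors_zero(self):
        assert scaled_cosine_error([1.0, 2.0], [1.0, 2.0], gamma=3) == pytest.approx(0.0)

    def test_orthogonal_gamma_one(self):
        assert scaled_cosine_error([1.0, 0.0], [0.0, 1.0], gamma=1) == pytest.approx(1.0)

    def test_known_value_gamma_two(self):
        expected = (1.0 - 1.0 / math.sqrt(2.0)) ** 2
        got = scaled_cosine_error([1.0, 0.0], [1.0, 1.0], gamma=2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0857864376, abs=1e-9)

    def test_zero_norm_contributes_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero-norm"):
            assert scaled_cosine_error([0.0, 0.0], [1.0, 0.0], gamma=2) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, z = rng.normal(size=4), rng.normal(size=4)
        for gamma in (1.0, 2.0, 3.0):
            assert scaled_cosine_error(x, z, gamma) == pytest.approx(
                sce_oracle(x, z, gamma), rel=1e-12
            )

    def test_gamma_damps_small_errors(self, rng):
        # with cosine error < 1, raising gamma never increases the term
        x = np.array([1.0, 0.1])
        z = np.array([1.0, 0.3])
        vals = [scaled_cosine_error(x, z, g) for g in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestReconstructionLoss:
    def test_perfect_reconstruction_zero(self, rng):
        X = rng.normal(size=(4, 3))
        plan = _plan(4, [0, 2], k=2, remasks=[[], []])
        assert reconstruction_loss(X, [X, X], plan, gamma=2) == pytest.approx(0.0)

    def test_linear_in_views(self, rng):
        X = rng.normal(size=(4, 3))
        Z = rng.normal(size=(4, 3))
        p1 = _plan(4, [1, 3], k=1)
        p2 = _plan(4, [1, 3], k=2, remasks=[[], []])
        l1 = reconstruction_loss(X, [Z], p1, gamma=2)
        l2 = reconstruction_loss(X, [Z, Z], p2, gamma=2)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_matches_brute_force_double_sum(self, rng):
        X = rng.normal(size=(4, 3))
        Z1, Z2 = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        masked = [0, 2]
        plan = _plan(4, masked, k=2, remasks=[[], []])
        expected = sum(
            sce_oracle(X[i], Z[i], 2.0) for Z in (Z1, Z2) for i in masked
        ) / len(masked)
        assert reconstruction_loss(X, [Z1, Z2], plan, gamma=2) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rows_outside_mask_do_not_contribute(self, rng):
        X = rng.normal(size=(4, 3))
        Z = rng.normal(size=(4, 3))
        plan = _plan(4, [1], k=1)
        base = reconstruction_loss(X, [Z], plan, gamma=2)
        Z2 = Z.copy()
        Z2[3] += 100.0  # unmasked row
        assert reconstruction_loss(X, [Z2], plan, gamma=2) == pytest.approx(base)

    def test_empty_mask_is_an_error(self, rng):
        plan = _plan(4, [], k=1)
        with pytest.raises(ValueError, match="nothing to reconstruct"):
            reconstruction_loss(rng.normal(size=(4, 3)), [np.ones((4, 3))], plan, 2)


def _identity_projector(d):
    return ProjectorParams(
        {"W1": np.eye(d), "b1": np.zeros(d), "W2": np.eye(d), "b2": np.zeros(d)}, d, d
    )


class TestRegularizationLoss:
    def test_equal_inputs_zero(self, rng):
        H = np.abs(rng.normal(size=(5, 3)))
        assert regularization_loss(H, H, _identity_projector(3), 2) == pytest.approx(0.0)

    def test_opposite_rows_gamma_one(self):
        H = np.abs(np.random.default_rng(0).normal(size=(3, 4))) + 0.1
        loss = regularization_loss(-H, H, _identity_projector(4), gamma=1)
        # ELU distorts negative values, so compute through the projector oracle
        proj = lambda M: np.where(M > 0, M, np.expm1(np.minimum(M, 0)))
        zb, xb = proj(-H), proj(H)
        expected = np.mean([sce_oracle(xb[i], zb[i], 1.0) for i in range(3)])
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_mean(self, rng):
        Hm = rng.normal(size=(3, 4))
        Hf = rng.normal(size=(3, 4))
        proj = _identity_projector(4)
        act = lambda M: np.where(M > 0, M, np.expm1(np.minimum(M, 0)))
        zb, xb = act(Hm), act(Hf)  # identity MLP still applies the hidden ELU
        expected = np.mean([sce_oracle(xb[i], zb[i], 2.0) for i in range(3)])
        assert regularization_loss(Hm, Hf, proj, gamma=2) == pytest.approx(
            expected, rel=1e-12
        )


def test_recon_config_validation():
    with pytest.raises(ValueError, match="gamma"):
        ReconLossConfig(gamma=0.5)
    with pytest.raises(ValueError, match="lambda"):
        ReconLossConfig(lambda1=-0.1)


def test_mask_plan_count_invariant():
    rng = np.random.default_rng(0)
    for n, rate in [(10, 0.3), (11, 0.5), (7, 0.9)]:
        plan = draw_mask_plan(n, rate, 1, rng)
        assert len(plan.masked_nodes) == int(np.rint(rate * n))
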