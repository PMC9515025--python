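"""The CE / multi-class Dice / batch Dice / class-adaptive Dice family,
cross-checked against independent triple-loop oracles."""

import math

import numpy as np
import pytest

from conftest import (
    loop_ca_dice,
    loop_cross_entropy,
    loop_multiclass_dice,
    loop_nnu_dice,
    random_tensor_pair,
)
from patchbalance import (
    LossConfig,
    as_one_hot,
    ca_dice,
    combined_loss,
    cross_entropy,
    multiclass_dice,
    nnu_dice,
)


def test_oracle_equivalence_on_random_tensors():
    """All four losses match brute-force loop implementations to 1e-9 on 50
    random small tensor pairs."""
    rng = np.random.default_rng(42)
    cfg = LossConfig()
    for _ in range(50):
        B = int(rng.integers(1, 3))
        C = int(rng.integers(2, 5))
        V = int(rng.integers(1, 28))
        P, G = random_tensor_pair(rng, B, C, V)
        assert cross_entropy(P, G, cfg) == pytest.approx(
            loop_cross_entropy(P, G), abs=1e-9
        )
        assert multiclass_dice(P, G, cfg) == pytest.approx(
            loop_multiclass_dice(P, G, cfg.epsilon), abs=1e-9
        )
        assert nnu_dice(P, G, cfg) == pytest.approx(
            loop_nnu_dice(P, G, cfg.epsilon), abs=1e-9
        )
        got = ca_dice(P, G, cfg)
        want, n = loop_ca_dice(P, G, cfg.epsilon)
        assert got.n_present == n
        if n:
            assert got.score == pytest.approx(want, abs=1e-9)
        else:
            assert math.isnan(got.score)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        G = as_one_hot(np.array([[[0, 1], [2, 1]]]), 3)
        assert cross_entropy(G, G) == pytest.approx(0.0, abs=1e-9)

    def test_half_confidence_single_voxel(self):
        P = np.array([[[0.5], [0.5]]])
        G = np.array([[[1.0], [0.0]]])
        assert cross_entropy(P, G) == pytest.approx(math.log(2), abs=1e-12)

    def test_per_batch_normalization(self):
        P = np.array([[[0.5, 0.5], [0.5, 0.5]]])
        G = np.array([[[1.0, 1.0], [0.0, 0.0]]])
        cfg = LossConfig(ce_normalization="per_batch")
        assert cross_entropy(P, G, cfg) == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_voxel_permutation_invariance(self):
        rng = np.random.default_rng(0)
        P, G = random_tensor_pair(rng, 2, 3, 10)
        perm = rng.permutation(10)
        assert cross_entropy(P, G) == pytest.approx(
            cross_entropy(P[:, :, perm], G[:, :, perm]), abs=1e-12
        )


class TestMulticlassDice:
    def test_perfect_overlap_near_one(self):
        G = as_one_hot(np.array([0, 1, 2, 1]), 3)
        assert multiclass_dice(G, G) == pytest.approx(1.0, abs=1e-4)

    def test_absent_class_scores_perfect_one(self):
        """The eps/eps artifact: a class missing from both prediction and
        ground truth is scored as perfectly segmented."""
        P = as_one_hot(np.array([0, 0, 0, 0]), 3).astype(float)
        G = as_one_hot(np.array([0, 0, 0, 0]), 3)
        # per-class terms: background ~1, class 1 and 2 exactly eps/eps = 1
        assert multiclass_dice(P, G) == pytest.approx(1.0, abs=1e-4)

    def test_hand_built_tensors_match_loop(self):
        P = np.array([[[0.7, 0.2, 0.1, 0.6], [0.3, 0.8, 0.9, 0.4]]])
        G = np.array([[[1.0, 0.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0]]])
        assert multiclass_dice(P, G) == pytest.approx(
            loop_multiclass_dice(P, G, 1e-5), abs=1e-12
        )


class TestNnuDice:
    def test_perfect_overlap_near_one(self):
        G = as_one_hot(np.array([0, 1, 2, 1]), 3)
        assert nnu_dice(G, G) == pytest.approx(1.0, abs=1e-4)

    def test_batch_pooling_differs_from_per_batch_average(self):
        """Class 1 exists only in batch 0: pooling sums over the batch gives
        a different value than averaging per-batch Dice terms."""
        rng = np.random.default_rng(1)
        P, _ = random_tensor_pair(rng, 2, 2, 6)
        G = np.zeros((2, 2, 6))
        G[0, 1, :3] = 1.0
        G[0, 0, 3:] = 1.0
        G[1, 0, :] = 1.0  # batch 1 is background-only
        pooled = nnu_dice(P, G)
        per_batch = np.mean([multiclass_dice(P[[b]], G[[b]]) for b in range(2)])
        assert pooled != pytest.approx(per_batch, abs=1e-6)

    def test_background_only_content_scores_one(self):
        G = as_one_hot(np.zeros(5, dtype=int), 3)
        assert nnu_dice(G, G) == pytest.approx(1.0, abs=1e-9)


class TestCaDice:
    def test_perfect_overlap_near_one(self):
        G = as_one_hot(np.array([0, 1, 2, 1]), 3)
        result = ca_dice(G, G)
        assert result.score == pytest.approx(1.0, abs=1e-4)
        assert result.n_present == 2

    def test_predicted_but_absent_class_not_counted(self):
        """G lacks class 2 but P predicts it: the term adds nothing to the
        numerator and nothing to N — CE, not Dice, carries the penalty."""
        G = as_one_hot(np.array([0, 1, 1, 0]), 3)
        P = as_one_hot(np.array([2, 1, 1, 2]), 3).astype(float)
        result = ca_dice(P, G)
        assert result.n_present == 1  # only class 1 counted
        with_correct_bg = ca_dice(G.astype(float), G)
        assert with_correct_bg.n_present == 1

    def test_hand_built_absent_class_matches_loop(self):
        rng = np.random.default_rng(2)
        P, _ = random_tensor_pair(rng, 1, 3, 8)
        G = np.zeros((1, 3, 8))
        G[0, 1, :5] = 1.0
        G[0, 0, 5:] = 1.0  # class 2 absent
        result = ca_dice(P, G)
        want, n = loop_ca_dice(P, G, 1e-5)
        assert result.n_present == n == 1
        assert result.score == pytest.approx(want, abs=1e-12)

    def test_undefined_when_no_foreground(self):
        G = as_one_hot(np.zeros(4, dtype=int), 3)
        result = ca_dice(G.astype(float), G)
        assert result.n_present == 0 and not result.defined
        assert math.isnan(result.score)

    def test_background_flag_counts_background(self):
        G = as_one_hot(np.zeros(4, dtype=int), 3)
        cfg = LossConfig(include_background_in_dice=True)
        result = ca_dice(G.astype(float), G, cfg)
        assert result.n_present == 1
        assert result.score == pytest.approx(1.0, abs=1e-4)

    def test_matches_nnu_dice_at_single_batch_all_present(self):
        """With B = 1 and every foreground class present the class-adaptive
        and batch formulations coincide as eps -> 0."""
        rng = np.random.default_rng(3)
        P, G = random_tensor_pair(rng, 1, 4, 30)
        assert all(G[0, c].sum() > 0 for c in range(4))
        cfg = LossConfig(epsilon=1e-12)
        assert ca_dice(P, G, cfg).score == pytest.approx(nnu_dice(P, G, cfg), abs=1e-6)


class TestInvariants:
    def test_class_permutation_invariance_of_dice_family(self):
        rng = np.random.default_rng(4)
        P, G = random_tensor_pair(rng, 2, 4, 12)
        perm = [0, 3, 1, 2]  # background fixed, foreground permuted
        Pp, Gp = P[:, perm], G[:, perm]
        assert multiclass_dice(P, G) == pytest.approx(multiclass_dice(Pp, Gp), abs=1e-12)
        assert nnu_dice(P, G) == pytest.approx(nnu_dice(Pp, Gp), abs=1e-12)
        assert ca_dice(P, G).score == pytest.approx(ca_dice(Pp, Gp).score, abs=1e-12)

    def test_voxel_permutation_invariance_of_dice_family(self):
        rng = np.random.default_rng(5)
        P, G = random_tensor_pair(rng, 1, 3, 20)
        perm = rng.permutation(20)
        Pp, Gp = P[:, :, perm], G[:, :, perm]
        assert multiclass_dice(P, G) == pytest.approx(multiclass_dice(Pp, Gp), abs=1e-12)
        assert ca_dice(P, G).score == pytest.approx(ca_dice(Pp, Gp).score, abs=1e-12)

    def test_ca_dice_bounded_above(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            P, G = random_tensor_pair(rng, 2, 3, 15)
            result = ca_dice(P, G)
            if result.defined:
                assert result.score <= 1.0 + 1e-9


class TestCombinedLoss:
    def test_perfect_prediction_near_zero(self):
        G = as_one_hot(np.array([0, 1, 2, 1]), 3)
        for kind in ("nnu", "ca"):
            assert combined_loss(G.astype(float), G, dice_kind=kind) == pytest.approx(
                0.0, abs=1e-3
            )

    def test_zero_dice_weight_equals_ce(self):
        rng = np.random.default_rng(7)
        P, G = random_tensor_pair(rng, 1, 3, 9)
        cfg = LossConfig(ce_weight=1.0, dice_weight=0.0)
        assert combined_loss(P, G, cfg, "ca") == pytest.approx(cross_entropy(P, G, cfg))

    def test_compositional(self):
        rng = np.random.default_rng(8)
        P, G = random_tensor_pair(rng, 2, 3, 11)
        cfg = LossConfig(ce_weight=0.5, dice_weight=2.0)
        want_nnu = 0.5 * cross_entropy(P, G, cfg) + 2.0 * (1 - nnu_dice(P, G, cfg))
        assert combined_loss(P, G, cfg, "nnu") == pytest.approx(want_nnu, abs=1e-12)
        want_ca = 0.5 * cross_entropy(P, G, cfg) + 2.0 * (1 - ca_dice(P, G, cfg).score)
        assert combined_loss(P, G, cfg, "ca") == pytest.approx(want_ca, abs=1e-12)

    def test_undefined_ca_dice_falls_back_to_ce(self):
        G = as_one_hot(np.zeros(6, dtype=int), 3)
        P = np.full((1, 3, 6), 1 / 3)
        assert combined_loss(P, G, dice_kind="ca") == pytest.approx(
            cross_entropy(P, G), abs=1e-12
        )


def test_shape_mismatch_rejected():
    P = np.full((1, 2, 4), 0.5)
    G = as_one_hot(np.zeros(5, dtype=int), 2)
    for fn in (cross_entropy, multiclass_dice, nnu_dice):
        with pytest.raises(ValueError):
            fn(P, G)
    with pytest.raises(ValueError):
        ca_dice(P, G)
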