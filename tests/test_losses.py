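"""Noise synthesis moments and contrastive-loss algebra."""

import numpy as np
import pytest

from sliceflow.autodiff import Tensor
from sliceflow.losses import (
    LossConfig,
    bgspp_loss,
    contrastive_loss,
    derangement,
    prl_loss,
    synthesize_anomalies,
    total_loss,
    triplet_loss,
)


class TestSynthesizeAnomalies:
    def test_zero_sigma_is_identity(self, rng):
        f = rng.normal(size=(100, 8))
        assert np.array_equal(synthesize_anomalies(f, 0.0, seed=1), f)

    def test_seed_contract(self, rng):
        f = rng.normal(size=(50, 4))
        a = synthesize_anomalies(f, 0.06, seed=3)
        b = synthesize_anomalies(f, 0.06, seed=3)
        c = synthesize_anomalies(f, 0.06, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_variance_moment(self):
        f = np.zeros(100_000)
        eps = synthesize_anomalies(f, 0.06, seed=0) - f
        assert abs(eps.var() - 0.0036) / 0.0036 < 0.05

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            synthesize_anomalies(np.zeros(3), -0.1, seed=0)


class TestTriplet:
    def test_margin_satisfied_gives_zero(self):
        # anchors equal their positive partners; negatives 2 below
        logp = np.array([1.0, 1.0, 1.0])
        logq = logp - 2.0
        assert float(triplet_loss(logp, logq, tau=1.0).data) == 0.0

    def test_degenerate_collapse_gives_tau(self):
        logp = np.full(4, 0.3)
        assert np.isclose(float(triplet_loss(logp, logp, tau=1.0).data), 1.0)

    def test_direct_evaluation(self):
        # 2 entries, derangement must swap: pairs (0,1) and (1,0)
        logp = np.array([0.0, 1.0])
        logq = np.array([-0.5, 1.0 - 0.5])
        # each term: max(0, 1 - 0.25 + 1) = 1.75
        assert np.isclose(float(triplet_loss(logp, logq, tau=1.0).data), 1.75)

    def test_requires_two_normals(self):
        with pytest.raises(ValueError, match="at least 2"):
            triplet_loss(np.array([1.0]), np.array([0.0]))

    def test_shift_invariance(self, rng):
        logp = rng.normal(size=10)
        logq = rng.normal(size=10)
        a = float(triplet_loss(logp, logq, tau=1.0, seed=2).data)
        b = float(triplet_loss(logp + 7.3, logq + 7.3, tau=1.0, seed=2).data)
        assert np.isclose(a, b)


class TestBgspp:
    def test_separated_batch_gives_zero(self):
        # normals at/above the boundary, perturbed at least tau below it
        logp = np.array([5.0, 5.0, 6.0, 8.0])
        b_n = np.percentile(logp, 10.0)
        assert b_n == 5.0
        logq = np.full(4, b_n - 2.0)
        assert float(bgspp_loss(logp, logq, beta=10.0, tau=1.0).data) == 0.0

    def test_hinge_arithmetic(self):
        # boundary at the single normal value; a second normal 1 below adds 1
        logp = np.array([2.0, 1.0])
        b_n = np.percentile(logp, 90.0)
        loss = bgspp_loss(logp, np.array([]), beta=90.0, tau=1.0)
        assert np.isclose(float(loss.data), (b_n - 1.0))
        # one perturbed entry exactly at the boundary contributes tau
        loss_q = bgspp_loss(np.array([3.0]), np.array([3.0]), beta=50.0, tau=1.0)
        assert np.isclose(float(loss_q.data), 1.0)

    def test_shift_invariance(self, rng):
        logp, logq = rng.normal(size=8), rng.normal(size=8)
        a = float(bgspp_loss(logp, logq).data)
        b = float(bgspp_loss(logp - 4.2, logq - 4.2).data)
        assert np.isclose(a, b)

    def test_monotone_in_logq(self, rng):
        logp, logq = rng.normal(size=8), rng.normal(size=8)
        base = float(bgspp_loss(logp, logq).data)
        bumped = logq.copy()
        bumped[3] += 1.5
        assert float(bgspp_loss(logp, bumped).data) >= base

    def test_empty_normals_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            bgspp_loss(np.array([]), np.array([1.0]))


class TestPrl:
    def test_separated_gives_zero(self):
        assert float(prl_loss(np.array([3.0, 4.0]), np.array([1.0, 2.0]), tau=1.0).data) == 0.0

    def test_equal_pair_gives_tau(self):
        assert np.isclose(float(prl_loss(np.array([0.5]), np.array([0.5]), tau=1.0).data), 1.0)

    def test_direct_evaluation(self):
        assert np.isclose(float(prl_loss(np.array([0.5]), np.array([0.2]), tau=1.0).data), 0.7)

    def test_full_pairing_mode(self):
        logp = np.array([1.0, 2.0])
        logq = np.array([0.5, 1.5])
        # pairs: (1,.5)=.5 (1,1.5)=1.5 (2,.5)=0 (2,1.5)=.5 with tau=1
        assert np.isclose(float(prl_loss(logp, logq, tau=1.0, pairs="full").data), 2.5)

    def test_shift_invariance_and_monotonicity(self, rng):
        logp, logq = rng.normal(size=6), rng.normal(size=6)
        a = float(prl_loss(logp, logq).data)
        assert np.isclose(a, float(prl_loss(logp + 2.0, logq + 2.0).data))
        bumped = logq.copy()
        bumped[0] += 0.5
        assert float(prl_loss(logp, bumped).data) >= a


def test_total_loss_composition():
    assert float(total_loss(2.0, 1.75, "triplet").data) == 3.75
    assert float(total_loss(2.0, 0.0, "triplet").data) == 2.0
    assert float(total_loss(2.0, 99.0, "none").data) == 2.0
    with pytest.raises(ValueError, match="finite"):
        total_loss(np.inf, 0.0, "triplet")


def test_contrastive_dispatch_and_nonnegativity(rng):
    logp = Tensor(rng.normal(size=12))
    logq = Tensor(rng.normal(size=12))
    for variant in ("triplet", "bgspp", "prl"):
        cfg = LossConfig(variant=variant, seed=1)
        assert float(contrastive_loss(logp, logq, cfg).data) >= 0.0
    assert float(contrastive_loss(logp, logq, LossConfig(variant="none")).data) == 0.0


def test_derangement_has_no_fixed_points():
    for n in (2, 5, 17):
        perm = derangement(n, seed=3)
        assert not np.any(perm == np.arange(n))
        assert sorted(perm) == list(range(n))


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(sigma=-0.1)
    with pytest.raises(ValueError):
        LossConfig(beta=0.0)
    with pytest.raises(ValueError):
        LossConfig(variant="hinge")
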