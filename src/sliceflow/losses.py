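"""Feature-space anomaly synthesis and contrastive boundary losses.

Anomalies are synthesized by adding i.i.d. Gaussian noise N(0, sigma^2)
(sigma = 0.06 by default) to the final per-location feature vectors. The
flow assigns scalar log-likelihoods log p_i to normal features and log q_i to
their perturbed counterparts, and a contrastive term shapes the boundary
between them:

* triplet  — sum_i max(0, (log p_i - log p_j)^2 - (log p_i - log q_i)^2 + tau),
  with j a seeded random derangement of the batch (the positive partner);
* bgspp    — boundary-guided semi-push-pull: hinges around b_n, the beta-th
  percentile of the normal log-likelihoods, pulling normals above b_n and
  pushing perturbed features below b_n - tau;
* prl      — pairwise ranking: max(0, tau - (log p_i - log q_j)) over pairs,
  index-aligned by default (full cross product available);
* none     — no contrastive term (flow objective alone).

The total training loss is the unweighted sum of the flow negative
log-likelihood and the selected contrastive term. All three contrastive
losses are invariant to adding a common constant to every log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossConfig",
    "synthesize_anomalies",
    "triplet_loss",
    "bgspp_loss",
    "prl_loss",
    "total_loss",
    "contrastive_loss",
]

VARIANTS = ("triplet", "bgspp", "prl", "none")


@dataclass(frozen=True)
class LossConfig:
    sigma: float = 0.06      # noise SD for feature-space anomaly synthesis
    tau: float = 1.0         # contrastive margin
    beta: float = 10.0       # percentile for the bgspp normal boundary b_n
    variant: str = "triplet"
    prl_pairs: str = "aligned"  # or "full"
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 < self.beta < 100:
            raise ValueError("beta must lie in (0, 100)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got '{self.variant}'")


def synthesize_anomalies(features: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Perturbed features f + eps, eps ~ iid N(0, sigma^2), reproducible by seed."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    features = np.asarray(features, dtype=np.float64)
    if sigma == 0:
        return features.copy()
    rng = np.random.default_rng([int(seed), 101])
    return features + rng.normal(0.0, sigma, size=features.shape)


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def derangement(n: int, seed: int) -> np.ndarray:
    """Seeded random derangement of range(n) (no fixed points), n >= 2."""
    rng = np.random.default_rng([int(seed), 202])
    idx = np.arange(n)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == idx):
            return perm


def triplet_loss(logp, logq, tau: float = 1.0, seed: int = 0) -> Tensor:
    """Batch-mean triplet term over scalar log-likelihoods.

    The anchor is log p_i, the positive partner log p_j is a random
    derangement of the normal batch, the negative is the paired perturbed
    log q_i.
    """
    logp, logq = _lift(logp), _lift(logq)
    n = logp.data.shape[0]
    if n < 2:
        raise ValueError("triplet loss needs at least 2 normal entries for a positive partner")
    if logq.data.shape[0] != n:
        raise ValueError("triplet loss requires paired log q of the same length as log p")
    j = derangement(n, seed)
    pos = (logp - logp[j]) ** 2
    neg = (logp - logq) ** 2
    return (pos - neg + tau).relu().mean()


def bgspp_loss(logp, logq, beta: float = 10.0, tau: float = 1.0) -> Tensor:
    """Boundary-guided semi-push-pull loss around the beta-th percentile b_n.

    b_n is treated as a constant of the batch during differentiation.
    """
    logp, logq = _lift(logp), _lift(logq)
    if logp.data.size == 0:
        raise ValueError("bgspp loss requires a non-empty normal batch")
    b_n = float(np.percentile(logp.data, beta))
    pull = (-(logp - b_n)).relu()          # |min(logp - b_n, 0)|
    push = (logq - b_n + tau).relu()       # |max(logq - b_n + tau, 0)|
    return pull.sum() + push.sum()


def prl_loss(logp, logq, tau: float = 1.0, pairs: str = "aligned") -> Tensor:
    """Pairwise ranking loss: hinge on the margin between log p and log q."""
    logp, logq = _lift(logp), _lift(logq)
    if logp.data.size == 0 or logq.data.size == 0:
        raise ValueError("prl loss requires non-empty batches")
    if pairs == "aligned":
        if logp.data.shape != logq.data.shape:
            raise ValueError("aligned prl pairing requires equal-length batches")
        return (tau - (logp - logq)).relu().sum()
    if pairs == "full":
        n, m = logp.data.shape[0], logq.data.shape[0]
        diff = logp.reshape(n, 1) - logq.reshape(1, m)
        return (tau - diff).relu().sum()
    raise ValueError(f"unknown prl pairing '{pairs}'")


def contrastive_loss(logp, logq, cfg: LossConfig) -> Tensor:
    """Dispatch the configured contrastive term ('none' contributes zero)."""
    if cfg.variant == "none":
        return Tensor(0.0)
    if cfg.variant == "triplet":
        return triplet_loss(logp, logq, tau=cfg.tau, seed=cfg.seed)
    if cfg.variant == "bgspp":
        return bgspp_loss(logp, logq, beta=cfg.beta, tau=cfg.tau)
    return prl_loss(logp, logq, tau=cfg.tau, pairs=cfg.prl_pairs)


def total_loss(flow_nll, contrastive, variant: str = "triplet"):
    """Unweighted sum of the flow objective and the contrastive term."""
    flow_nll = _lift(flow_nll)
    if not np.isfinite(flow_nll.data).all():
        raise ValueError("flow objective is not finite")
    if variant == "none":
        return flow_nll
    contrastive = _lift(contrastive)
    if not np.isfinite(contrastive.data).all():
        raise ValueError("contrastive term is not finite")
    return flow_nll + contrastive
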