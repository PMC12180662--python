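"""Conditional normalizing flow over per-location feature vectors.

A RealNVP-style stack of affine coupling layers. Each layer permutes the
channels (fixed seeded permutation, undone at the layer's exit so an
identity-initialized flow is the identity map), splits them in half, and
updates the second half with an affine map whose scale and shift come from a
two-linear-layer ReLU subnet fed with the first half concatenated with a 2D
sinusoidal positional code. Scales are soft-clamped, s <- alpha*tanh(s/alpha),
to keep the log-det Jacobian bounded.

Under a standard-normal base density the log-likelihood is

    log p(x) = -d/2 log(2 pi) - ||phi(x)||^2 / 2 + log|det d phi / dx|,

and the training objective is the mean negative log-likelihood.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor, concat, permute_cols

__all__ = [
    "FlowModel",
    "positional_condition",
    "log_likelihood",
    "nll_objective",
]

LOG_2PI = float(np.log(2.0 * np.pi))


def positional_condition(h0: int, w0: int, condition_dim: int) -> np.ndarray:
    """Fixed sinusoidal 2D positional code, shape (h0*w0, condition_dim).

    The first half of the channels encodes the row index, the second half the
    column index, each on a geometric frequency ladder with interleaved
    sine/cosine. Values lie in [-1, 1] and depend only on (h, w, h0, w0).
    """
    if h0 <= 0 or w0 <= 0:
        raise ValueError("grid dimensions must be positive")
    if condition_dim % 2 != 0 or condition_dim <= 0:
        raise ValueError(f"condition_dim must be a positive even integer, got {condition_dim}")
    half = condition_dim // 2

    def axis_code(positions: np.ndarray) -> np.ndarray:
        i = np.arange(half)
        freqs = 1.0 / (10000.0 ** ((i - (i % 2)) / max(half, 1)))
        angles = positions[:, None] * freqs[None, :]
        code = np.where(np.arange(half)[None, :] % 2 == 0, np.sin(angles), np.cos(angles))
        return code

    rows, cols = np.meshgrid(np.arange(h0), np.arange(w0), indexing="ij")
    return np.concatenate(
        [axis_code(rows.ravel().astype(np.float64)), axis_code(cols.ravel().astype(np.float64))],
        axis=1,
    )


class FlowModel:
    """Affine coupling flow with positional conditioning.

    Parameters
    ----------
    dim : feature dimension d (512 at full scale).
    condition_dim : width of the positional code appended to each subnet input.
    n_coupling : number of coupling layers (default 8).
    hidden : subnet hidden width (two linear layers, one ReLU between).
    clamp : soft-clamp bound alpha for the log-scales.
    seed : seeds the channel permutations and subnet initialization.

    Subnets are identity-initialized (final linear map zero), so a freshly
    constructed flow is the identity transform with zero log-det.
    """

    def __init__(self, dim: int, condition_dim: int = 128, n_coupling: int = 8,
                 hidden: int = 512, clamp: float = 1.9, seed: int = 0,
                 dtype=np.float64):
        if dim < 2:
            raise ValueError("flow dimension must be >= 2")
        self.dim = int(dim)
        self.condition_dim = int(condition_dim)
        self.n_coupling = int(n_coupling)
        self.hidden = int(hidden)
        self.clamp = float(clamp)
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        self.d1 = dim // 2
        self.d2 = dim - self.d1
        rng = np.random.default_rng([self.seed, 13])
        self.perms = [rng.permutation(dim) for _ in range(n_coupling)]
        self.inv_perms = [np.argsort(p) for p in self.perms]
        self.params: list[Tensor] = []
        self._layers = []
        fan_in = self.d1 + self.condition_dim
        for _ in range(n_coupling):
            w1 = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, hidden)).astype(self.dtype),
                        requires_grad=True)
            b1 = Tensor(np.zeros(hidden, dtype=self.dtype), requires_grad=True)
            w2 = Tensor(np.zeros((hidden, 2 * self.d2), dtype=self.dtype), requires_grad=True)  # identity init
            b2 = Tensor(np.zeros(2 * self.d2, dtype=self.dtype), requires_grad=True)
            self._layers.append((w1, b1, w2, b2))
            self.params.extend((w1, b1, w2, b2))

    # -- forward / inverse ------------------------------------------------------
    def _subnet_np(self, xa: np.ndarray, cond: np.ndarray, layer) -> tuple[np.ndarray, np.ndarray]:
        w1, b1, w2, b2 = layer
        h = np.maximum(np.concatenate([xa, cond], axis=1) @ w1.data + b1.data, 0.0)
        st = h @ w2.data + b2.data
        s = self.clamp * np.tanh(st[:, : self.d2] / self.clamp)
        return s, st[:, self.d2 :]

    def forward(self, x: np.ndarray, cond: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Numpy forward: returns (z, logdet), each length-N along axis 0."""
        x = self._check(x, cond)
        logdet = np.zeros(x.shape[0])
        h = x
        for perm, inv, layer in zip(self.perms, self.inv_perms, self._layers):
            hp = h[:, perm]
            xa, xb = hp[:, : self.d1], hp[:, self.d1 :]
            s, t = self._subnet_np(xa, cond, layer)
            yb = xb * np.exp(s) + t
            h = np.concatenate([xa, yb], axis=1)[:, inv]
            logdet += s.sum(axis=1)
        return h, logdet

    def inverse(self, z: np.ndarray, cond: np.ndarray) -> np.ndarray:
        z = self._check(z, cond)
        h = z
        for perm, inv, layer in zip(
            reversed(self.perms), reversed(self.inv_perms), reversed(self._layers)
        ):
            hp = h[:, perm]
            za, zb = hp[:, : self.d1], hp[:, self.d1 :]
            s, t = self._subnet_np(za, cond, layer)
            xb = (zb - t) * np.exp(-s)
            h = np.concatenate([za, xb], axis=1)[:, inv]
        return h

    def forward_tensor(self, x: Tensor, cond: Tensor) -> tuple[Tensor, Tensor]:
        """Autodiff forward used during training."""
        n = x.shape[0]
        logdet = Tensor(np.zeros(n, dtype=x.data.dtype))
        h = x
        for perm, inv, layer in zip(self.perms, self.inv_perms, self._layers):
            w1, b1, w2, b2 = layer
            hp = permute_cols(h, perm, inv)
            xa = hp[:, : self.d1]
            xb = hp[:, self.d1 :]
            hid = (concat([xa, cond], axis=1) @ w1 + b1).relu()
            st = hid @ w2 + b2
            s = (st[:, : self.d2] / self.clamp).tanh() * self.clamp
            t = st[:, self.d2 :]
            yb = xb * s.exp() + t
            h = permute_cols(concat([xa, yb], axis=1), inv, perm)
            logdet = logdet + s.sum(axis=1)
        return h, logdet

    # -- fast training path: hand-written backprop ------------------------------
    def log_likelihood_and_cache(self, x: np.ndarray, cond: np.ndarray):
        """Forward pass keeping per-layer intermediates for manual backprop.

        Functionally identical to :func:`log_likelihood`; used during training
        where building the autodiff graph over volume-sized batches would
        dominate the runtime. Gradients from :meth:`backward_from_dlogp` are
        verified against the autodiff path in the test suite.
        """
        x = self._check(x, cond)
        cond = np.asarray(cond, dtype=x.dtype)
        cache = []
        h = x
        logdet = np.zeros(x.shape[0], dtype=x.dtype)
        for perm, inv, layer in zip(self.perms, self.inv_perms, self._layers):
            w1, b1, w2, b2 = layer
            hp = h[:, perm]
            xa, xb = hp[:, : self.d1], hp[:, self.d1 :]
            inp = np.concatenate([xa, cond], axis=1)
            hr = np.maximum(inp @ w1.data + b1.data, 0.0)
            st = hr @ w2.data + b2.data
            s = self.clamp * np.tanh(st[:, : self.d2] / self.clamp)
            t = st[:, self.d2 :]
            es = np.exp(s)
            yb = xb * es + t
            h = np.concatenate([xa, yb], axis=1)[:, inv]
            logdet += s.sum(axis=1)
            cache.append(dict(xb=xb, inp=inp, hr=hr, s=s, es=es))
        logp = -0.5 * self.dim * LOG_2PI - 0.5 * (h**2).sum(axis=1) + logdet
        return logp, (cache, h)

    def backward_from_dlogp(self, cache_state, dlogp: np.ndarray) -> list[np.ndarray]:
        """Parameter gradients of sum_i dlogp_i * logp_i, in params order."""
        cache, z = cache_state
        dlogp = np.asarray(dlogp, dtype=z.dtype)
        dh = -z * dlogp[:, None]
        grads: list[np.ndarray] = [None] * (4 * self.n_coupling)
        for k in range(self.n_coupling - 1, -1, -1):
            perm, inv = self.perms[k], self.inv_perms[k]
            w1, b1, w2, b2 = self._layers[k]
            c = cache[k]
            dcpl = dh[:, perm]  # backward of out = cpl[:, inv]
            dxa = dcpl[:, : self.d1].copy()
            dyb = dcpl[:, self.d1 :]
            dxb = dyb * c["es"]
            ds = dyb * c["xb"] * c["es"] + dlogp[:, None]  # affine + log-det terms
            dt = dyb
            dsr = ds * (1.0 - (c["s"] / self.clamp) ** 2)
            dst = np.concatenate([dsr, dt], axis=1)
            grads[4 * k + 2] = c["hr"].T @ dst          # dW2
            grads[4 * k + 3] = dst.sum(axis=0)          # db2
            dhr = dst @ w2.data.T
            dh1 = dhr * (c["hr"] > 0)
            grads[4 * k + 0] = c["inp"].T @ dh1         # dW1
            grads[4 * k + 1] = dh1.sum(axis=0)          # db1
            dinp = dh1 @ w1.data.T
            dxa += dinp[:, : self.d1]
            dh = np.concatenate([dxa, dxb], axis=1)[:, inv]  # backward of hp = h[:, perm]
        return grads

    def _check(self, x: np.ndarray, cond: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2 or x.shape[1] != self.dim:
            raise ValueError(f"expected input of shape (N, {self.dim}), got {x.shape}")
        cond = np.asarray(cond)
        if cond.shape != (x.shape[0], self.condition_dim):
            raise ValueError(
                f"expected condition of shape ({x.shape[0]}, {self.condition_dim}), got {cond.shape}"
            )
        return x

    # -- persistence ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.params)}
        state["config"] = np.array(
            [self.dim, self.condition_dim, self.n_coupling, self.hidden, self.seed],
            dtype=np.int64,
        )
        state["clamp"] = np.array([self.clamp])
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.data = np.asarray(state[f"p{i}"], dtype=self.dtype)

    @classmethod
    def from_state_dict(cls, state: dict[str, np.ndarray]) -> "FlowModel":
        dim, cond_dim, n_coupling, hidden, seed = (int(v) for v in state["config"])
        flow = cls(dim, condition_dim=cond_dim, n_coupling=n_coupling, hidden=hidden,
                   clamp=float(state["clamp"][0]), seed=seed,
                   dtype=state["p0"].dtype)
        flow.load_state_dict(state)
        return flow


def log_likelihood(x: np.ndarray, cond: np.ndarray, model: FlowModel) -> np.ndarray:
    """Per-vector log p(x) under the flow (standard-normal base density)."""
    z, logdet = model.forward(x, cond)
    return -0.5 * model.dim * LOG_2PI - 0.5 * (z**2).sum(axis=1) + logdet


def log_likelihood_tensor(x: Tensor, cond: Tensor, model: FlowModel) -> Tensor:
    z, logdet = model.forward_tensor(x, cond)
    return (z * z).sum(axis=1) * (-0.5) + logdet + (-0.5 * model.dim * LOG_2PI)


def nll_objective(x: np.ndarray, cond: np.ndarray, model: FlowModel) -> float:
    """Mean negative log-likelihood over the batch (the flow training loss)."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("empty batch")
    return float(-log_likelihood(x, cond, model).mean())


def make_optimizer(model: FlowModel, lr: float = 1e-3) -> Adam:
    return Adam(model.params, lr=lr)
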