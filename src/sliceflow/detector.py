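"""Scikit-learn style estimator wrapping the full slice-flow pipeline.

``SliceFlowDetector`` is fit on normal volumes only (unsupervised): each
volume's axial slices are encoded by a frozen backbone, depth-aggregated, and
the conditional normalizing flow is trained on the per-voxel feature vectors
with the flow negative log-likelihood plus a contrastive boundary term
computed against noise-synthesized anomalous features. One volume is one
training batch. Scoring produces per-voxel anomaly maps.

The estimator composes with sklearn tooling (``get_params`` / ``set_params``
/ ``clone``); fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from . import cnf
from .autodiff import Adam, Tensor
from .backbones import BackboneAdapter, get_backbone
from .encoder import EncoderConfig, encode_slice
from .losses import LossConfig, contrastive_loss, synthesize_anomalies, total_loss
from .pipeline import AnomalyMap, aggregate_volume, score_volume
from .volio import Volume

__all__ = ["SliceFlowDetector", "encode_volume"]


def encode_volume(data: np.ndarray, backbone: BackboneAdapter, config: EncoderConfig) -> np.ndarray:
    """Encode every axial slice of a (D, H, W) volume -> (D, C, H0, W0).

    All slices go through the backbone as one batch; the result is identical
    to stacking :func:`sliceflow.encoder.encode_slice` per slice (asserted in
    the test suite).
    """
    from scipy import ndimage
    from skimage.transform import resize as _sk_resize

    from .encoder import reduce_channels

    data = data.data if isinstance(data, Volume) else np.asarray(data)
    batch = np.repeat(np.asarray(data, dtype=np.float64)[:, None, :, :],
                      backbone.in_channels, axis=1)
    feats = backbone.extract(batch)  # {layer: (D, C_l, H_l, W_l)}
    p = config.patch_size
    layers = sorted(feats)
    aggregated = {
        l: ndimage.uniform_filter(feats[l], size=(1, 1, p, p), mode="nearest") if p > 1
        else feats[l]
        for l in layers
    }
    d0, _, h0, w0 = aggregated[layers[0]].shape
    fused = []
    for l in layers:
        g = aggregated[l]
        if g.shape[2:] != (h0, w0):
            g = _sk_resize(g, (g.shape[0], g.shape[1], h0, w0), order=1,
                           preserve_range=True, anti_aliasing=False)
        fused.append(g)
    fused = np.concatenate(fused, axis=1)  # (D, C, H0, W0)
    out = np.empty((d0, config.target_dim, h0, w0))
    for j in range(d0):
        out[j] = reduce_channels(fused[j], config.target_dim)
    return out


class SliceFlowDetector(BaseEstimator):
    """Unsupervised anomaly localization for 3D volumes.

    Parameters mirror the reference configuration at full scale (wide
    residual backbone, 512-dim embedding, 8 coupling layers, sigma 0.06,
    tau 1.0, Adam lr 0.001, one volume per batch); pass ``backbone='tiny'``
    with a smaller ``target_dim`` for CPU-scale runs.
    """

    def __init__(
        self,
        backbone: str = "wide_resnet50_2",
        tap_layers: tuple[int, ...] = (2, 3),
        patch_size: int = 3,
        target_dim: int = 512,
        n_coupling: int = 8,
        hidden: int = 512,
        condition_dim: int = 128,
        clamp: float = 1.9,
        sigma: float = 0.06,
        tau: float = 1.0,
        beta: float = 10.0,
        loss_variant: str = "triplet",
        agg_window: int = 3,
        smooth_sigma: float = 1.0,
        epochs: int = 5,
        lr: float = 1e-3,
        grad_clip: float = 10.0,
        avg_epochs: int = 2,
        seed: int = 0,
    ):
        self.backbone = backbone
        self.tap_layers = tap_layers
        self.patch_size = patch_size
        self.target_dim = target_dim
        self.n_coupling = n_coupling
        self.hidden = hidden
        self.condition_dim = condition_dim
        self.clamp = clamp
        self.sigma = sigma
        self.tau = tau
        self.beta = beta
        self.loss_variant = loss_variant
        self.agg_window = agg_window
        self.smooth_sigma = smooth_sigma
        self.epochs = epochs
        self.lr = lr
        self.grad_clip = grad_clip
        self.avg_epochs = avg_epochs
        self.seed = seed

    # -- fitting ---------------------------------------------------------------
    def _make_backbone(self) -> BackboneAdapter:
        if isinstance(self.backbone, BackboneAdapter):
            return self.backbone
        return get_backbone(self.backbone, seed=self.seed, tap_layers=tuple(self.tap_layers))

    def fit(self, X, y=None, precomputed_features=None):
        """Fit the flow on normal volumes.

        X : sequence of (D, H, W) arrays or Volumes (training is unsupervised;
        a non-None y must mark every volume as normal, e.g. zeros).
        precomputed_features : optional list of (D, C, H0, W0) arrays from
        :func:`encode_volume` with this estimator's backbone and encoder
        config, to avoid re-encoding when fitting several variants.
        """
        if y is not None and np.any(np.asarray(y) != 0):
            raise ValueError("training is unsupervised: all training volumes must be normal (y == 0)")
        self.backbone_ = self._make_backbone()
        self.encoder_config_ = EncoderConfig(patch_size=self.patch_size, target_dim=self.target_dim)
        if precomputed_features is None:
            feats = [encode_volume(v, self.backbone_, self.encoder_config_) for v in X]
        else:
            feats = [np.asarray(f) for f in precomputed_features]
        if not feats:
            raise ValueError("fit requires at least one training volume")
        grids = [aggregate_volume(list(f), w=self.agg_window).values for f in feats]
        h0, w0 = grids[0].shape[2], grids[0].shape[3]
        self.grid_shape_ = (h0, w0)
        # global (scalar) feature standardization: brings the embedding to
        # unit scale so the noise SD sigma and margin tau retain the meaning
        # they have for unit-scale pretrained embeddings
        allv = np.concatenate([g.ravel() for g in grids])
        self.feature_loc_ = float(allv.mean())
        scale = float(allv.std())
        self.feature_scale_ = scale if scale > 0 else 1.0
        del allv
        self.flow_ = cnf.FlowModel(
            dim=self.target_dim, condition_dim=self.condition_dim,
            n_coupling=self.n_coupling, hidden=self.hidden, clamp=self.clamp,
            seed=self.seed, dtype=np.float32,
        )
        self.cond_ = cnf.positional_condition(h0, w0, self.condition_dim).astype(np.float32)
        opt = Adam(self.flow_.params, lr=self.lr, clip_norm=self.grad_clip)
        loss_cfg = LossConfig(sigma=self.sigma, tau=self.tau, beta=self.beta,
                              variant=self.loss_variant, seed=self.seed)
        self.loss_log_ = []
        step = 0
        # tail (stochastic-weight) averaging over the final epochs damps the
        # step-to-step parameter noise of volume-sized batches
        avg_from = max(0, int(self.epochs) - int(self.avg_epochs)) if self.avg_epochs else int(self.epochs)
        avg_sums = None
        avg_count = 0
        for epoch in range(int(self.epochs)):
            for grid in grids:
                d = grid.shape[0]
                vectors = grid.transpose(0, 2, 3, 1).reshape(-1, self.target_dim)
                vectors = (vectors - self.feature_loc_) / self.feature_scale_
                cond = np.tile(self.cond_, (d, 1))
                perturbed = synthesize_anomalies(vectors, self.sigma,
                                                 seed=self.seed * 100003 + step)
                x_all = np.concatenate([vectors, perturbed], axis=0).astype(np.float32)
                c_all = np.concatenate([cond, cond], axis=0).astype(np.float32)
                # flow forward with cached intermediates (manual backprop),
                # loss head differentiated by the autodiff engine
                logall, cache = self.flow_.log_likelihood_and_cache(x_all, c_all)
                t = Tensor(logall.astype(np.float64), requires_grad=True)
                n = vectors.shape[0]
                logp, logq = t[:n], t[n:]
                flow_nll = logp.mean() * (-1.0)
                step_cfg = LossConfig(sigma=self.sigma, tau=self.tau, beta=self.beta,
                                      variant=self.loss_variant,
                                      seed=loss_cfg.seed * 31 + step)
                contrast = contrastive_loss(logp, logq, step_cfg)
                loss = total_loss(flow_nll, contrast, variant=self.loss_variant)
                loss.backward()
                for p, g in zip(self.flow_.params, self.flow_.backward_from_dlogp(cache, t.grad)):
                    p.grad = g
                opt.step()
                self.loss_log_.append(
                    dict(epoch=epoch, step=step, nll=float(flow_nll.data),
                         contrastive=float(np.asarray(contrast.data)),
                         total=float(loss.data))
                )
                step += 1
                if epoch >= avg_from:
                    if avg_sums is None:
                        avg_sums = [p.data.astype(np.float64).copy() for p in self.flow_.params]
                    else:
                        for s, p in zip(avg_sums, self.flow_.params):
                            s += p.data
                    avg_count += 1
        if avg_count > 0:
            for p, s in zip(self.flow_.params, avg_sums):
                p.data = (s / avg_count).astype(p.data.dtype)
        return self

    # -- scoring ---------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "flow_"):
            raise NotFittedError("SliceFlowDetector is not fitted; call fit first")

    def score_volumes(self, X, precomputed_features=None) -> list[AnomalyMap]:
        """Raw anomaly maps (one per volume), at the input resolution."""
        self._check_fitted()
        maps = []
        for i, v in enumerate(X):
            feats = None
            if precomputed_features is not None:
                feats = aggregate_volume(list(np.asarray(precomputed_features[i])),
                                         w=self.agg_window)
            maps.append(
                score_volume(v, self.backbone_, self.flow_,
                             config=self.encoder_config_, w=self.agg_window,
                             smooth_sigma=self.smooth_sigma,
                             feature_loc=self.feature_loc_,
                             feature_scale=self.feature_scale_,
                             features=feats)
            )
        return maps

    def decision_function(self, X) -> np.ndarray:
        """Pooled per-slice anomaly scores (max pixel score per axial slice)."""
        maps = self.score_volumes(X)
        return np.concatenate([m.scores.max(axis=(1, 2)) for m in maps])
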