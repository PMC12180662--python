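"""Encoder-decoder contrast (EDC): backbone fine-tuning on 2D images.

Before anomaly training, the pretrained 2D feature extractor can be adapted
to the target imaging domain on an *independent* set of 2D images. A decoder
mirroring the tapped encoder stages (transposed convolutions) reconstructs
the encoder's feature pyramid from its deepest tap, and both are trained with
a global cosine distance in which the encoder-branch targets are
stop-gradients:

    L = sum_l [ 1 - cos( sg(flatten(f_E^l)), flatten(f_D^l) ) ].

Gradients reach the encoder only through the decoder's *input* (the forward
values of the deepest encoder feature), never through the stop-gradient
targets. After fine-tuning, the encoder is frozen; this loss plays no part in
the anomaly-localization training stage.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Adam, Tensor, conv_transpose2d
from .backbones import TinyCNNAdapter

__all__ = ["EncoderDecoderPair", "global_cosine_loss", "finetune_backbone"]


class EncoderDecoderPair:
    """A trainable encoder adapter plus a transposed-conv mirror decoder.

    The decoder mirrors only the tapped encoder stages: it maps the deepest
    tapped feature back up the pyramid, producing one reconstruction grid per
    tapped layer with exactly the encoder grid's shape.
    """

    def __init__(self, encoder: TinyCNNAdapter, seed: int = 0):
        if encoder.frozen:
            raise ValueError("EDC needs a trainable encoder (construct with trainable=True)")
        self.encoder = encoder
        taps = sorted(encoder.tap_layers)
        self.taps = taps
        rng = np.random.default_rng([int(seed), 31])
        # one transposed-conv stage per gap from the deepest tap upward
        self._stages: list[tuple[int, Tensor, Tensor]] = []
        chans = encoder.channels
        levels = list(reversed(taps))
        for src, dst in zip(levels[:-1], levels[1:]):
            cin, cout = chans[src], chans[dst]
            w = Tensor(
                rng.normal(0.0, np.sqrt(2.0 / (cin * 9)), size=(cin, cout, 3, 3)),
                requires_grad=True,
            )
            b = Tensor(np.zeros(cout), requires_grad=True)
            self._stages.append((dst, w, b))
        # refinement conv at the deepest level so the decoder has capacity there
        cdeep = chans[levels[0]]
        self._deep_w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / (cdeep * 9)), size=(cdeep, cdeep, 3, 3)),
            requires_grad=True,
        )
        self._deep_b = Tensor(np.zeros(cdeep), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        ps = [self._deep_w, self._deep_b]
        for _, w, b in self._stages:
            ps.extend((w, b))
        return ps + self.encoder.parameters()

    def decoder_parameters(self) -> list[Tensor]:
        ps = [self._deep_w, self._deep_b]
        for _, w, b in self._stages:
            ps.extend((w, b))
        return ps

    def forward(self, x: Tensor) -> tuple[dict[int, Tensor], dict[int, Tensor]]:
        """Return (encoder taps, decoder reconstructions), shape-matched per tap."""
        enc = self.encoder.forward_tensors(x)
        enc = {l: enc[l] for l in self.taps}
        deepest = self.taps[-1]
        h = conv_transpose2d(enc[deepest], self._deep_w, self._deep_b, stride=1, padding=1)
        dec = {deepest: h}
        for dst, w, b in self._stages:
            h = conv_transpose2d(h.relu(), w, b, stride=2, padding=1, output_padding=1)
            dec[dst] = h
        for l in self.taps:
            if dec[l].shape != enc[l].shape:
                raise ValueError(
                    f"decoder output shape {dec[l].shape} does not match encoder tap "
                    f"layer {l} shape {enc[l].shape}"
                )
        return enc, dec


def _flat_cos(a: Tensor, b: Tensor) -> Tensor:
    """Cosine similarity of the flattened grids (single scalar)."""
    af = a.reshape(-1)
    bf = b.reshape(-1)
    num = (af * bf).sum()
    den = ((af * af).sum().sqrt()) * ((bf * bf).sum().sqrt())
    return num / den


def global_cosine_loss(enc_feats, dec_feats) -> Tensor:
    """Sum over layers of 1 - cosine of the flattened grids.

    The encoder branch is detached (stop-gradient): gradients flow only
    through ``dec_feats``. Accepts lists of numpy arrays or Tensors.
    """
    if len(enc_feats) != len(dec_feats):
        raise ValueError(
            f"layer count mismatch: {len(enc_feats)} encoder vs {len(dec_feats)} decoder grids"
        )
    loss = Tensor(0.0)
    for l, (fe, fd) in enumerate(zip(enc_feats, dec_feats)):
        fe = fe if isinstance(fe, Tensor) else Tensor(np.asarray(fe, dtype=np.float64))
        fd = fd if isinstance(fd, Tensor) else Tensor(np.asarray(fd, dtype=np.float64))
        if fe.shape != fd.shape:
            raise ValueError(f"shape mismatch at layer index {l}: {fe.shape} vs {fd.shape}")
        loss = loss + (1.0 - _flat_cos(fe.detach(), fd))
    return loss


def finetune_backbone(
    images, pair: EncoderDecoderPair, epochs: int = 1, lr: float = 1e-3,
    log: list | None = None,
) -> TinyCNNAdapter:
    """Fine-tune the encoder with the stop-gradient global cosine loss.

    ``images`` is a sequence of 2D arrays (normalized intensities). Returns
    the fine-tuned encoder as a *frozen* adapter for downstream feature
    extraction; per-step losses are appended to ``log`` when given.
    """
    images = list(images)
    if not images:
        raise ValueError("finetune_backbone requires a non-empty image set")
    if epochs > 0:
        opt = Adam(pair.parameters(), lr=lr)
        for _ in range(int(epochs)):
            for img in images:
                x = Tensor(pair.encoder._prepare(np.asarray(img)))
                enc, dec = pair.forward(x)
                loss = global_cosine_loss(
                    [enc[l] for l in pair.taps], [dec[l] for l in pair.taps]
                )
                opt.zero_grad()
                loss.backward()
                opt.step()
                if log is not None:
                    log.append(float(loss.data))
    tuned = pair.encoder.copy()
    tuned.frozen = True
    for p in tuned.parameters():
        p.requires_grad = False
    return tuned
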