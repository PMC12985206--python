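"""Network components: masked encoders, cross-omics attention, gated residual fusion.

The architecture is a mid-fusion design.  Each omics modality passes
through its own stack of pathway-masked linear layers (connectivity fixed
by the prior; the binary mask is re-applied on every forward pass so that
unsupported weights can never leak signal).  The per-modality pathway
embeddings then interact through scaled dot-product attention over the
modality axis, a two-layer sigmoid gate softly selects fused features,
and a residual mean of the raw embeddings is added back before a linear
classifier head produces the binary staging logit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate

__all__ = ["MaskedLinear", "Encoder", "CrossAttention", "GateFusion", "FusionNetwork"]


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class MaskedLinear(Module):
    """Affine layer whose weights are Hadamard-masked by a fixed binary matrix.

    The mask multiplies the weight matrix inside every forward pass, so a
    masked-out entry contributes nothing regardless of its stored value.
    """

    def __init__(self, mask: np.ndarray, rng: np.random.Generator, slope: float = 0.01):
        if not np.isin(mask, (0.0, 1.0)).all():
            raise ValueError("mask must be binary")
        self.mask = Tensor(np.asarray(mask, dtype=np.float64))
        fan_in = mask.shape[0]
        w = _kaiming(rng, fan_in, mask.shape) * mask  # zero masked positions after init
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(mask.shape[1]), requires_grad=True)
        self.slope = slope

    def __call__(self, x: Tensor, activate: bool = True) -> Tensor:
        if x.shape[-1] != self.mask.shape[0]:
            raise ValueError(
                f"input dim {x.shape[-1]} does not match mask input dim {self.mask.shape[0]}"
            )
        pre = x @ (self.weight * self.mask) + self.bias
        return pre.leaky_relu(self.slope) if activate else pre


class Encoder(Module):
    """Per-modality stack of masked linear layers with dropout on hidden layers."""

    def __init__(
        self,
        masks: list[np.ndarray],
        rng: np.random.Generator,
        slope: float = 0.01,
        dropout: float = 0.3,
    ):
        self.layers = [MaskedLinear(m, rng, slope) for m in masks]
        self.dropout = dropout

    def __call__(
        self,
        x: Tensor,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, list[Tensor]]:
        """Return the pathway embedding and every intermediate activation."""
        activations: list[Tensor] = []
        h = x
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if training and self.dropout > 0 and i < n - 1:
                keep = (rng.uniform(size=h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * Tensor(keep)
            activations.append(h)
        return h, activations


class CrossAttention(Module):
    """Single-head scaled dot-product attention over the modality axis."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.wq = Tensor(_kaiming(rng, dim, (dim, dim)), requires_grad=True)
        self.wk = Tensor(_kaiming(rng, dim, (dim, dim)), requires_grad=True)
        self.wv = Tensor(_kaiming(rng, dim, (dim, dim)), requires_grad=True)
        self.dim = dim

    def __call__(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """``h``: (batch, m, dim) stacked modality embeddings.

        Returns attended embeddings (batch, m, dim) and the row-stochastic
        raw attention matrix (batch, m, m).
        """
        q = h @ self.wq
        k = h @ self.wk
        v = h @ self.wv
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dim))
        attn = scores.softmax(axis=-1)
        return attn @ v, attn


class GateFusion(Module):
    """Two-layer sigmoid gate with residual mean-of-modalities fusion.

    z stacks the attended modality-pathway features (length m*dim); the
    gate g = sigma(W2 GELU(W1 z + b1) + b2) selects components of z, and
    h_fuse = W_f (g * z) + mean_i h_i adds back the average raw embedding.
    """

    def __init__(self, n_modalities: int, dim: int, hidden: int, rng: np.random.Generator):
        zdim = n_modalities * dim
        self.w1 = Tensor(_kaiming(rng, zdim, (zdim, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(_kaiming(rng, hidden, (hidden, zdim)), requires_grad=True)
        self.b2 = Tensor(np.zeros(zdim), requires_grad=True)
        self.wf = Tensor(_kaiming(rng, zdim, (zdim, dim)), requires_grad=True)
        self.n_modalities = n_modalities
        self.dim = dim

    def __call__(self, attended: Tensor, raw: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """``attended``/``raw``: (batch, m, dim).  Returns (h_fuse, g, z)."""
        b = attended.shape[0]
        z = attended.reshape(b, self.n_modalities * self.dim)
        g = (z @ self.w1 + self.b1).gelu() @ self.w2 + self.b2
        g = g.sigmoid()
        residual = raw.mean(axis=1)
        h_fuse = (g * z) @ self.wf + residual
        return h_fuse, g, z


class FusionNetwork(Module):
    """Full mid-fusion classifier: encoders -> attention -> gate -> logit."""

    def __init__(
        self,
        masks: list[np.ndarray],
        n_modalities: int,
        seed: int = 0,
        slope: float = 0.01,
        dropout: float = 0.3,
        gate_hidden: int | None = None,
        modality_dropout: float = 1.0 / 3.0,
    ):
        rng = np.random.default_rng(seed)
        self.encoders = [Encoder(masks, rng, slope, dropout) for _ in range(n_modalities)]
        self.dim = masks[-1].shape[1]
        self.n_modalities = n_modalities
        self.attention = CrossAttention(self.dim, rng)
        self.fusion = GateFusion(n_modalities, self.dim, gate_hidden or self.dim, rng)
        self.head_w = Tensor(_kaiming(rng, self.dim, (self.dim, 1)), requires_grad=True)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)
        # training-time missing-modality simulation (sample-wise zeroing);
        # realizes modularity to absent modalities and blocks co-adapted
        # memorization through any single omics layer
        self.modality_dropout = modality_dropout

    def forward(
        self,
        xs: list[Tensor],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Run the network on one batch (a list of (batch, genes) tensors).

        Returns a dict with the logit, the attention matrix, the
        per-sample modality weights (column means of the attention matrix,
        renormalized to sum to one) and all intermediate activations.
        """
        if len(xs) != self.n_modalities:
            raise ValueError(
                f"expected {self.n_modalities} modalities, got {len(xs)}"
            )
        if training and self.modality_dropout > 0 and self.n_modalities > 1:
            batch = xs[0].shape[0]
            keep = rng.uniform(size=(batch, self.n_modalities)) >= self.modality_dropout
            xs = [x * Tensor(keep[:, j:j + 1].astype(float)) for j, x in enumerate(xs)]
        embeddings = []
        encoder_activations = []
        for enc, x in zip(self.encoders, xs):
            h, acts = enc(x, training=training, rng=rng)
            embeddings.append(h.reshape(h.shape[0], 1, self.dim))
            encoder_activations.append(acts)
        stacked = concatenate(embeddings, axis=1)  # (batch, m, dim)
        attended, attn = self.attention(stacked)
        h_fuse, gate, z = self.fusion(attended, stacked)
        logit = (h_fuse @ self.head_w + self.head_b).reshape(h_fuse.shape[0])
        col_mean = attn.mean(axis=1)  # attention received by each modality
        weights = col_mean / col_mean.sum(axis=-1, keepdims=True)
        return {
            "logit": logit,
            "attention": attn,
            "modality_weights": weights,
            "embeddings": stacked,
            "attended": attended,
            "h_fuse": h_fuse,
            "gate": gate,
            "z": z,
            "encoder_activations": encoder_activations,
        }

    __call__ = forward

    # ------------------------------------------------------------- state I/O
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("parameter count mismatch")
        for i, p in enumerate(params):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float64).reshape(p.data.shape)
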