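"""Late-integration autoencoder for multi-omics embedding.

The network reconstructs the concatenated per-cell-line omics vector
``x = (x_1, ..., x_4n)`` (four omics blocks of ``n`` genes each) through four
stages:

* an **omics-specific encoder** — two dense layers applied independently to
  each omics block (implemented as block-diagonal weight matrices, so no
  cross-omics mixing happens before integration);
* an **omics-integration encoder** — two dense layers mapping the concatenated
  per-omics codes ``h = (h_1, h_2, h_3, h_4)`` to the bottleneck embedding
  ``z``;
* mirrored **integration** and **omics-specific decoders**.

Hidden layers use relu activations, ``y = relu(W x + b)``; the final
reconstruction layer is linear so arbitrary-signed inputs are reachable.  The
loss is mean squared reconstruction error plus a weight penalty: squared-norm
(L2) by default, with an L1 option.  Optimization is full-batch Adam with
manually derived gradients; everything is plain numpy and deterministic given
the seed.

Reference defaults mirror a genome-scale setting (2048/1024 specific,
1024/256 integration neurons); tests and small fixtures use scaled-down sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pertpath.embedding import OMICS_ORDER
from pertpath.preprocess import GeneCentricMatrix

logger = logging.getLogger(__name__)

__all__ = ["LateIntegrationAutoencoder", "train_autoencoder", "AutoencoderCodes"]

N_OMICS = 4


def _block_diag_mask(in_per_block: int, out_per_block: int) -> np.ndarray:
    """Mask keeping only within-omics weights in a (4*in, 4*out) matrix."""
    mask = np.zeros((N_OMICS * in_per_block, N_OMICS * out_per_block))
    for b in range(N_OMICS):
        mask[
            b * in_per_block : (b + 1) * in_per_block,
            b * out_per_block : (b + 1) * out_per_block,
        ] = 1.0
    return mask


class _Dense:
    """One dense layer with optional structural mask and relu/linear activation."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        relu: bool = True,
        mask: np.ndarray | None = None,
    ) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.relu = relu
        self.mask = mask
        if mask is not None:
            self.W *= mask
        # Adam state
        self._mW = np.zeros_like(self.W)
        self._vW = np.zeros_like(self.W)
        self._mb = np.zeros_like(self.b)
        self._vb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._pre: np.ndarray | None = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        pre = x @ self.W + self.b
        out = np.maximum(pre, 0.0) if self.relu else pre
        if cache:
            self._x, self._pre = x, pre
        return out

    def backward(self, grad_out: np.ndarray, l2: float, l1: bool) -> np.ndarray:
        if self.relu:
            grad_out = grad_out * (self._pre > 0)
        gW = self._x.T @ grad_out
        if l2 > 0:
            gW = gW + (l2 * np.sign(self.W) if l1 else 2.0 * l2 * self.W)
        if self.mask is not None:
            gW *= self.mask
        self._gW = gW
        self._gb = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def adam_step(self, lr: float, t: int, beta1: float = 0.9, beta2: float = 0.999) -> None:
        eps = 1e-8
        for p, g, m, v in (
            (self.W, self._gW, self._mW, self._vW),
            (self.b, self._gb, self._mb, self._vb),
        ):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        if self.mask is not None:
            self.W *= self.mask

    def weight_sqnorm(self) -> float:
        return float(np.sum(self.W**2))

    def weight_abs(self) -> float:
        return float(np.sum(np.abs(self.W)))


@dataclass
class AutoencoderCodes:
    """Trained embedding plus its provenance record."""

    z: np.ndarray  # (cells, latent)
    model: "LateIntegrationAutoencoder"
    final_loss: float
    loss_history: list[float]
    l2: float
    epochs: int
    seed: int
    architecture: dict = field(default_factory=dict)

    @property
    def latent_dim(self) -> int:
        return self.z.shape[1]


class LateIntegrationAutoencoder:
    """Numpy implementation of the four-stage late-integration autoencoder."""

    def __init__(
        self,
        n_genes: int,
        specific_sizes: tuple[int, int] = (2048, 1024),
        integration_sizes: tuple[int, int] = (1024, 256),
        l2: float = 0.0,
        penalty: str = "l2",
        seed: int = 0,
    ) -> None:
        if penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        self.n_genes = n_genes
        self.specific_sizes = tuple(specific_sizes)
        self.integration_sizes = tuple(integration_sizes)
        self.l2 = float(l2)
        self.penalty = penalty
        self.seed = int(seed)
        self.trained = False

        rng = np.random.default_rng(seed)
        s1, s2 = self.specific_sizes
        i1, lat = self.integration_sizes
        self.latent_dim = lat
        # Encoder: omics-specific stack (block-diagonal), then integration.
        self.encoder = [
            _Dense(N_OMICS * n_genes, N_OMICS * s1, rng, mask=_block_diag_mask(n_genes, s1)),
            _Dense(N_OMICS * s1, N_OMICS * s2, rng, mask=_block_diag_mask(s1, s2)),
            _Dense(N_OMICS * s2, i1, rng),
            _Dense(i1, lat, rng),
        ]
        # Decoder mirrors; final reconstruction layer is linear.
        self.decoder = [
            _Dense(lat, i1, rng),
            _Dense(i1, N_OMICS * s2, rng),
            _Dense(N_OMICS * s2, N_OMICS * s1, rng, mask=_block_diag_mask(s2, s1)),
            _Dense(
                N_OMICS * s1,
                N_OMICS * n_genes,
                rng,
                relu=False,
                mask=_block_diag_mask(s1, n_genes),
            ),
        ]

    # -- forward passes ----------------------------------------------------

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Forward pass through the encoder only; rows are cell lines."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != N_OMICS * self.n_genes:
            raise ValueError(
                f"expected {N_OMICS * self.n_genes} input features, got {x.shape[1]}"
            )
        for layer in self.encoder:
            x = layer.forward(x)
        return x

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"expected latent dim {self.latent_dim}, got {z.shape[1]}")
        for layer in self.decoder:
            z = layer.forward(z)
        return z

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(x))

    def decoder_activation(self, feature: int) -> np.ndarray:
        """Per-gene activation of a one-hot latent feature pushed through the decoder.

        Returns an array of length ``n_genes``: the gene-wise sum of absolute
        activations over the four omics slots of the reconstruction layer.
        """
        if not self.trained:
            raise RuntimeError("decoder not trained; call fit() first")
        e = np.zeros((1, self.latent_dim))
        e[0, feature] = 1.0
        out = self.decode(e)[0]
        return np.abs(out.reshape(N_OMICS, self.n_genes)).sum(axis=0)

    # -- training ----------------------------------------------------------

    def loss(self, x: np.ndarray) -> float:
        mse = float(np.mean((x - self.reconstruct(x)) ** 2))
        return mse + self.l2 * self.weight_penalty()

    def weight_penalty(self) -> float:
        layers = self.encoder + self.decoder
        if self.penalty == "l1":
            return sum(l.weight_abs() for l in layers)
        return sum(l.weight_sqnorm() for l in layers)

    def weight_sqnorm(self) -> float:
        return sum(l.weight_sqnorm() for l in self.encoder + self.decoder)

    def fit(
        self,
        x: np.ndarray,
        epochs: int = 500,
        lr: float = 1e-3,
        patience: int | None = 50,
        min_delta: float = 1e-7,
    ) -> list[float]:
        """Full-batch Adam on MSE + weight penalty; returns the loss history.

        Early stopping halts when the loss has not improved by ``min_delta``
        for ``patience`` consecutive epochs (``patience=None`` disables it).
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        layers = self.encoder + self.decoder
        history: list[float] = []
        best = np.inf
        stall = 0
        l1 = self.penalty == "l1"
        for epoch in range(1, epochs + 1):
            h = x
            for layer in layers:
                h = layer.forward(h, cache=True)
            resid = h - x
            mse = float(np.mean(resid**2))
            loss = mse + self.l2 * self.weight_penalty()
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (mse={mse}); lower the learning rate"
                )
            history.append(loss)
            grad = 2.0 * resid / resid.size
            for layer in reversed(layers):
                grad = layer.backward(grad, self.l2, l1)
            for layer in layers:
                layer.adam_step(lr, epoch)
            if patience is not None:
                if loss < best - min_delta:
                    best, stall = loss, 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
        self.trained = True
        return history


def train_autoencoder(
    matrices: Sequence[GeneCentricMatrix] | np.ndarray,
    specific_sizes: tuple[int, int] = (2048, 1024),
    integration_sizes: tuple[int, int] = (1024, 256),
    l2: float = 0.0,
    penalty: str = "l2",
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
) -> AutoencoderCodes:
    """Train the late-integration autoencoder on the four omics layers.

    ``matrices`` may be the four :class:`GeneCentricMatrix` layers (stacked in
    the fixed omics order into per-cell concatenated vectors) or an already
    concatenated ``(cells, 4*n_genes)`` array.
    """
    if isinstance(matrices, np.ndarray):
        x = np.asarray(matrices, dtype=float)
        if x.shape[1] % N_OMICS:
            raise ValueError("feature count must be a multiple of 4 (omics blocks)")
        n_genes = x.shape[1] // N_OMICS
    else:
        by_kind = {m.omics_kind: m for m in matrices}
        missing = set(OMICS_ORDER) - set(by_kind)
        if missing:
            raise ValueError(f"missing omics layers: {sorted(missing)}")
        blocks = [by_kind[k].values.to_numpy(dtype=float) for k in OMICS_ORDER]
        n_genes = blocks[0].shape[1]
        x = np.concatenate(blocks, axis=1)
    model = LateIntegrationAutoencoder(
        n_genes, specific_sizes, integration_sizes, l2=l2, penalty=penalty, seed=seed
    )
    history = model.fit(x, epochs=epochs, lr=lr)
    z = model.encode(x)
    return AutoencoderCodes(
        z=z,
        model=model,
        final_loss=history[-1],
        loss_history=history,
        l2=l2,
        epochs=len(history),
        seed=seed,
        architecture={
            "specific_sizes": list(specific_sizes),
            "integration_sizes": list(integration_sizes),
            "n_genes": n_genes,
            "penalty": penalty,
        },
    )
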