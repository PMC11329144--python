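"""Contrastive (InfoNCE / NT-Xent) loss and the supervised training loss.

For a minibatch of N recordings, each cropped twice, embeddings are ordered
so that positions (2k, 2k+1) hold the two crops of recording k.  With
``sim(u, v)`` the cosine similarity and temperature ``tau``,

    l(i, j) = -log[ exp(sim(z_i, z_j)/tau) / sum_{k != i} exp(sim(z_i, z_k)/tau) ]
    L       = (1/2N) * sum_k [ l(2k, 2k+1) + l(2k+1, 2k) ]

The denominator excludes only k = i, so at N = 1 the loss is identically 0,
and for 2N identical embeddings L = log(2N - 1).

Embeddings are L2-normalized before the similarity computation, which makes
the dot product the cosine exactly.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor

__all__ = [
    "cosine_sim",
    "infonce_pair_loss",
    "infonce_batch_loss",
    "infonce_loss_graph",
    "bce_loss_graph",
]


def cosine_sim(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity ``u.v / (|u||v|)``; raises on a zero vector."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(u @ v / (nu * nv))


def _normalized_sims(Z: np.ndarray, tau: float) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise ValueError("zero embedding in batch")
    Zn = Z / norms
    return (Zn @ Zn.T) / tau


def infonce_pair_loss(i: int, j: int, Z: np.ndarray, tau: float) -> float:
    """The loss ``l(i, j)`` of one ordered positive pair (0-based indices)."""
    Z = np.asarray(Z, dtype=np.float64)
    two_n = Z.shape[0]
    if two_n < 2 or two_n % 2:
        raise ValueError("Z must hold 2N >= 2 embeddings")
    if not (0 <= i < two_n and 0 <= j < two_n) or i == j:
        raise ValueError("indices must be distinct and in range")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    s = _normalized_sims(Z, tau)[i]
    mask = np.ones(two_n, dtype=bool)
    mask[i] = False
    m = s[mask].max()
    log_denominator = m + np.log(np.exp(s[mask] - m).sum())
    return float(log_denominator - s[j])


def infonce_batch_loss(Z: np.ndarray, tau: float) -> float:
    """Vectorized batch loss L over 2N pair-ordered embeddings."""
    Z = np.asarray(Z, dtype=np.float64)
    two_n = Z.shape[0]
    if two_n < 2 or two_n % 2:
        raise ValueError("Z must hold 2N >= 2 embeddings")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    s = _normalized_sims(Z, tau)
    np.fill_diagonal(s, -np.inf)  # the indicator 1_{k != i}
    m = s.max(axis=1, keepdims=True)
    log_denominator = (m + np.log(np.exp(s - m).sum(axis=1, keepdims=True)))[:, 0]
    pos = np.arange(two_n) ^ 1  # partner index: 0<->1, 2<->3, ...
    positive_sims = s[np.arange(two_n), pos]
    return float(np.mean(log_denominator - positive_sims))


def infonce_loss_graph(Z: Tensor, tau: float) -> Tensor:
    """Differentiable batch loss on a (2N, D) embedding tensor."""
    two_n = Z.shape[0]
    if two_n < 2 or two_n % 2:
        raise ValueError("Z must hold 2N >= 2 embeddings")
    norms = ((Z * Z).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    Zn = Z / norms
    s = (Zn @ Zn.transpose(1, 0)) * (1.0 / tau)
    # exclude the diagonal from the denominator; sims/tau are bounded by
    # 1/tau so a fixed offset keeps exp() in range without a max-shift
    eye = Tensor(np.eye(two_n, dtype=np.float32))
    s_off = s - eye * (1.0 / tau + 60.0)
    log_denominator = s_off.exp().sum(axis=1).log()
    pos = np.arange(two_n) ^ 1
    partner = Tensor(np.eye(two_n, dtype=np.float32)[pos])
    positive_sims = (s * partner).sum(axis=1)
    return (log_denominator - positive_sims).mean()


def bce_loss_graph(logits: Tensor, targets: np.ndarray, eps: float = 1e-7) -> Tensor:
    """One-hot binary cross-entropy over the two sigmoid outputs."""
    t = Tensor(np.asarray(targets, dtype=np.float32))
    s = logits.sigmoid()
    return -((t * (s + eps).log() + (1.0 - t) * ((1.0 - s) + eps).log()).mean())
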