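"""Training objectives: cross-view InfoNCE, supervised contrastive, prediction.

All three accept either numpy arrays or autodiff :class:`~metaddi.nn.Tensor`
inputs and return a scalar Tensor, so the same code path serves closed-form
unit tests and backpropagation.  Similarity is cosine throughout, scaled by a
temperature ``tau``.

The combined objective is  L = L_s + alpha * (L_uc + L_sc):  prediction
cross-entropy plus a weighted sum of the unsupervised cross-view loss and the
supervised contrastive loss over drug-pair embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class LossConfig:
    """Temperature and balance coefficient; cosine similarity is fixed."""

    tau: float = 0.05
    alpha: float = 0.1
    similarity: str = "cosine"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature tau must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.similarity != "cosine":
            raise ValueError("only cosine similarity is supported")


def _l2_normalize_rows(z: Tensor) -> Tensor:
    z = nn.as_tensor(z)
    norms = (z * z).sum(axis=1, keepdims=True) ** 0.5
    if (norms.data <= 0).any():
        raise ValueError("zero-norm embedding row: cosine similarity undefined")
    return z / norms


def _logsumexp_rows(s: Tensor) -> Tensor:
    shift = Tensor(s.data.max(axis=1, keepdims=True))
    return nn.log(nn.exp(s - shift).sum(axis=1, keepdims=True)) + shift


def info_nce_views(z_c, z_f, tau: float) -> Tensor:
    """Symmetric cross-view InfoNCE over all drugs.

    The positive for drug i in one view is the same drug in the other view;
    the denominator runs over all |D| candidates of the other view (positive
    included).  The two directional sums are averaged with a 1/(2|D|) factor.
    """
    z_c, z_f = nn.as_tensor(z_c), nn.as_tensor(z_f)
    if z_c.shape != z_f.shape:
        raise ValueError("view embeddings must have matching shapes")
    zc = _l2_normalize_rows(z_c)
    zf = _l2_normalize_rows(z_f)
    s = (zc @ zf.T) * (1.0 / tau)           # (|D|, |D|) cross-view similarities
    pos = s.diag()                           # s(z_i^C, z_i^F)
    lse_rows = _logsumexp_rows(s).reshape(-1)
    lse_cols = _logsumexp_rows(s.T).reshape(-1)
    n = s.shape[0]
    return ((lse_rows - pos).sum() + (lse_cols - pos).sum()) * (1.0 / (2 * n))


def supervised_contrastive(pair_emb, labels, tau: float) -> Tensor:
    """Supervised contrastive loss over a batch of drug-pair embeddings.

    Positives for an anchor are the other batch members with the same event
    label; the denominator runs over all other batch members.  The anchor is
    excluded from both.  Anchors without positives are excluded from the
    outer average; a batch of size < 2 returns 0.
    """
    pair_emb = nn.as_tensor(pair_emb)
    labels = np.asarray(labels)
    b = pair_emb.shape[0]
    if b < 2:
        import logging
        logging.getLogger(__name__).warning(
            "supervised contrastive loss on a batch of size %d is 0", b)
        return Tensor(0.0)
    z = _l2_normalize_rows(pair_emb)
    s = (z @ z.T) * (1.0 / tau)
    same = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)                       # positives exclude anchor
    off_diag = 1.0 - np.eye(b)
    # log denominator per anchor over the other batch members
    neg = np.where(off_diag > 0, s.data, -np.inf)
    shift = Tensor(neg.max(axis=1, keepdims=True))
    denom = nn.log((nn.exp(s - shift) * Tensor(off_diag)).sum(axis=1, keepdims=True)) + shift
    log_prob = s - denom                              # (b, b)
    n_pos = same.sum(axis=1)
    anchors = n_pos > 0
    if not anchors.any():
        return Tensor(0.0)
    per_anchor = (log_prob * Tensor(same)).sum(axis=1) * Tensor(
        np.where(anchors, 1.0 / np.maximum(n_pos, 1.0), 0.0))
    return -(per_anchor.sum() * (1.0 / anchors.sum()))


def prediction_loss(probs, labels) -> Tensor:
    """Mean cross-entropy of predicted event probabilities.

    ``probs`` rows must sum to 1; probabilities are clipped at 1e-12 before
    the log.
    """
    probs = nn.as_tensor(probs)
    labels = np.asarray(labels, dtype=np.intp)
    if not np.allclose(probs.data.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n = probs.shape[0]
    onehot = np.zeros_like(probs.data)
    onehot[np.arange(n), labels] = 1.0
    true_p = (probs * Tensor(onehot)).sum(axis=1)
    return -(nn.log(true_p).mean())


def total_loss(l_s, l_uc, l_sc, alpha: float) -> Tensor:
    """L = L_s + alpha * (L_uc + L_sc)."""
    return nn.as_tensor(l_s) + alpha * (nn.as_tensor(l_uc) + nn.as_tensor(l_sc))
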