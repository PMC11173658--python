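"""Two-view drug encoder: graph attention per graph, semantic attention across.

Both contrastive views share the feature transform h_i = sigma(W x_i + b) but
use independent attention parameter sets per graph.  The *average view*
attends over the support of the mean of the clean sub-graph adjacencies; the
*augmented view* encodes each (possibly corrupted) per-meta-path sub-graph
and fuses them with a learned semantic softmax over meta-paths.

Attention per head k on a graph:

    e_ij   = LeakyReLU(a_k^T [h_i || h_j])          (a_k in R^{2d})
    alpha  = softmax over the neighborhood of i (self-loop included)
    z_i^k  = PReLU(sum_j alpha_ij W_k h_j + b)      (W_k in R^{(d/H) x d})
    z_i    = concat_k z_i^k                          (dimension d)

Neighbor aggregation uses h_j; a ``self_aggregate`` switch replaces it with
the anchor's own h_i for comparison.  Semantic attention scores each graph by
q1^T mean_i tanh(W1 z_i + b1), softmax-normalizes the scores into weights
beta, and returns z_i^F = sum_P beta_P z_i^P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .metapath import SubGraphSet
from .nn import Tensor

LEAKY_SLOPE = 0.2
AVERAGE_VIEW = "avg"


@dataclass
class GraphAttentionParams:
    """One multi-head attention parameter set (per graph)."""

    a: list            # per head: Tensor of shape (2d,)
    W: list            # per head: Tensor of shape (d/H, d)
    b: Tensor          # shared bias, shape (d/H,)
    prelu_slope: Tensor  # learnable scalar

    def tensors(self) -> list[Tensor]:
        return [*self.a, *self.W, self.b, self.prelu_slope]


@dataclass
class EncoderParams:
    """All learnable encoder tensors.

    ``graph_params`` holds one :class:`GraphAttentionParams` per graph name:
    the average view plus each meta-path sub-graph.
    """

    W: Tensor                    # (d, F) feature transform
    b: Tensor                    # (d,)
    graph_params: dict           # name -> GraphAttentionParams
    W1: Tensor                   # (d, d) semantic transform
    b1: Tensor                   # (d,)
    q1: Tensor                   # (d,) semantic query
    d: int
    n_heads: int
    activation: str = "elu"
    self_aggregate: bool = False
    extra: dict = field(default_factory=dict)

    def tensors(self) -> list[Tensor]:
        out = [self.W, self.b, self.W1, self.b1, self.q1]
        for name in sorted(self.graph_params):
            out.extend(self.graph_params[name].tensors())
        return out


def init_graph_attention(rng: np.random.Generator, d: int, n_heads: int) -> GraphAttentionParams:
    head_dim = d // n_heads
    return GraphAttentionParams(
        a=[nn.xavier_uniform(rng, (2 * d,)) for _ in range(n_heads)],
        W=[nn.xavier_uniform(rng, (head_dim, d)) for _ in range(n_heads)],
        b=nn.parameter(np.zeros(head_dim)),
        prelu_slope=nn.parameter(np.array(0.25)),
    )


def init_encoder_params(
    rng: np.random.Generator,
    n_features: int,
    d: int,
    n_heads: int,
    graph_names: list[str],
    activation: str = "elu",
    self_aggregate: bool = False,
) -> EncoderParams:
    """Xavier-uniform initialization of every encoder tensor.

    One attention parameter set is created per graph name plus one for the
    average view.  ``d`` must be divisible by ``n_heads``.
    """
    if d % n_heads != 0:
        raise ValueError("embedding size d must be divisible by the number of heads")
    gp = {AVERAGE_VIEW: init_graph_attention(rng, d, n_heads)}
    for name in graph_names:
        gp[name] = init_graph_attention(rng, d, n_heads)
    return EncoderParams(
        W=nn.xavier_uniform(rng, (d, n_features)),
        b=nn.parameter(np.zeros(d)),
        graph_params=gp,
        W1=nn.xavier_uniform(rng, (d, d)),
        b1=nn.parameter(np.zeros(d)),
        q1=nn.xavier_uniform(rng, (d,)),
        d=d,
        n_heads=n_heads,
        activation=activation,
        self_aggregate=self_aggregate,
    )


def _activate(x: Tensor, kind: str) -> Tensor:
    if kind == "elu":
        return nn.elu(x)
    if kind == "relu":
        return nn.relu(x)
    if kind == "tanh":
        return nn.tanh(x)
    raise ValueError(f"unknown activation {kind!r}")


def transform_features(X, params: EncoderParams) -> Tensor:
    """h_i = sigma(W x_i + b) for every drug, as rows of a |D| x d matrix."""
    X = nn.as_tensor(X)
    if not np.isfinite(X.data).all():
        raise ValueError("non-finite entries in the drug feature matrix")
    return _activate(X @ params.W.T + params.b, params.activation)


def gat_encode(
    adjacency: np.ndarray,
    h: Tensor,
    gp: GraphAttentionParams,
    self_aggregate: bool = False,
    return_attention: bool = False,
):
    """Multi-head attention aggregation over one drug graph.

    Self-loops are added internally so isolated drugs still attend to
    themselves.  Returns the |D| x d embedding matrix (and per-head attention
    matrices when requested).
    """
    n = adjacency.shape[0]
    mask = (np.asarray(adjacency) > 0).astype(float)
    np.fill_diagonal(mask, 1.0)
    d = h.shape[1]
    n_heads = len(gp.a)
    # all heads batched: scores (H, n, n), aggregation via batched matmul
    a_stack = nn.stack(gp.a).T                              # (2d, H)
    s1 = h @ a_stack.take_rows(np.arange(d))                # (n, H): a^T h_i part
    s2 = h @ a_stack.take_rows(np.arange(d, 2 * d))         # (n, H): a^T h_j part
    e = nn.leaky_relu(s1.T.reshape(n_heads, n, 1) + s2.T.reshape(n_heads, 1, n),
                      LEAKY_SLOPE)
    alpha = nn.masked_softmax(e, mask[None, :, :], axis=2)  # rows sum to 1 on support
    hw = nn.stack([h @ W_k.T for W_k in gp.W])              # (H, n, d/H)
    if self_aggregate:
        agg = alpha.sum(axis=2, keepdims=True) * hw         # sum_j alpha_ij * (W h_i)
    else:
        agg = nn.bmm(alpha, hw)                             # sum_j alpha_ij * (W h_j)
    z_heads = nn.prelu(agg + gp.b, gp.prelu_slope)          # (H, n, d/H)
    z = z_heads.transpose(1, 0, 2).reshape(n, d)            # concat over heads
    if return_attention:
        return z, [alpha.data[k] * mask for k in range(n_heads)]
    return z


def average_adjacency(sgs: SubGraphSet) -> np.ndarray:
    """Mean of the clean sub-graph adjacencies; entries lie in [0, 1]."""
    if len(sgs) == 0:
        raise ValueError("empty sub-graph set")
    return np.mean([g.astype(float) for g in sgs.graphs], axis=0)


def encode_average_view(sgs: SubGraphSet, h: Tensor, params: EncoderParams,
                        use_edge_weights: bool = False,
                        return_attention: bool = False):
    """Encode drugs on the average graph view.

    The neighborhood of drug i is the nonzero support of row i of the mean
    adjacency; fractional edge weights are not fed into attention unless
    ``use_edge_weights`` (attention re-learns edge importance).
    """
    m_c = average_adjacency(sgs)
    support = m_c if use_edge_weights else (m_c > 0).astype(float)
    return gat_encode(support, h, params.graph_params[AVERAGE_VIEW],
                      self_aggregate=params.self_aggregate,
                      return_attention=return_attention)


def semantic_fuse(z_list: list[Tensor], params: EncoderParams,
                  return_beta: bool = True):
    """Fuse per-sub-graph embeddings with semantic attention.

    beta_P = softmax_P( q1^T mean_i tanh(W1 z_i^P + b1) );
    z_i^F  = sum_P beta_P z_i^P.
    """
    if not z_list:
        raise ValueError("semantic_fuse requires at least one sub-graph embedding")
    scores = []
    for z in z_list:
        s = nn.tanh(z @ params.W1.T + params.b1).mean(axis=0)   # (d,)
        scores.append((s * params.q1).sum())
    e = nn.stack(scores)                                        # (l,)
    beta = nn.softmax(e, axis=0)
    z_f = None
    for p, z in enumerate(z_list):
        term = beta.take_rows([p]).reshape(1, 1) * z
        z_f = term if z_f is None else z_f + term
    if return_beta:
        return beta, z_f
    return z_f


def encode_augmented_view(sgs: SubGraphSet, h: Tensor, params: EncoderParams,
                          return_beta: bool = False):
    """Per-sub-graph attention encoding followed by semantic fusion."""
    z_list = []
    for g, name in zip(sgs.graphs, sgs.names):
        z_list.append(gat_encode(g, h, params.graph_params[name],
                                 self_aggregate=params.self_aggregate))
    beta, z_f = semantic_fuse(z_list, params)
    if return_beta:
        return beta, z_f
    return z_f
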