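"""Meta-path instance counting, PathSim similarity and top-K sub-graphs.

A meta-path is a node-type sequence starting and ending at drugs, e.g.
D–C–D (two drugs sharing a chemical substructure) or the 3-hop D–P–P–D
(two drugs whose target proteins interact).  Path-instance counts are matrix
products of the incidence chain; PathSim normalizes them as

    s(i, j) = 2 * p_ij / (p_ii + p_jj)

so that a pair is similar when many of their paths are shared relative to the
paths each drug has to itself.  Each meta-path induces a drug–drug sub-graph
that keeps, per drug, only the K most similar neighbors.

The canonical meta-path order is DCD, DPD, DED, DTD, DPPD, restricted to the
attribute types actually present in the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hg import DrugHG

CANONICAL_ORDER = ("DCD", "DPD", "DED", "DTD", "DPPD")

# meta-path name -> attribute type letter of the intermediate node(s)
_METAPATH_TYPE = {"DCD": "C", "DPD": "P", "DED": "E", "DTD": "T", "DPPD": "P"}


class MetaPathUnavailable(ValueError):
    pass


@dataclass(frozen=True)
class MetaPathSpec:
    """A drug-to-drug meta-path, resolvable against a :class:`DrugHG`."""

    name: str

    def __post_init__(self):
        if self.name not in _METAPATH_TYPE:
            raise ValueError(f"unknown meta-path {self.name!r}")

    @property
    def attribute_type(self) -> str:
        return _METAPATH_TYPE[self.name]

    def available_in(self, hg: DrugHG) -> bool:
        t = self.attribute_type
        if t not in hg.incidence:
            return False
        if self.name == "DPPD" and hg.ppi is None:
            return False
        return True


@dataclass
class SubGraphSet:
    """Binary symmetric drug–drug adjacencies, one per meta-path."""

    graphs: list          # list of |D| x |D| 0/1 ndarrays, zero diagonal
    names: list           # meta-path names, same order
    k_values: list        # the K used per graph

    def __len__(self) -> int:
        return len(self.graphs)

    def copy(self) -> "SubGraphSet":
        return SubGraphSet([g.copy() for g in self.graphs], list(self.names),
                          list(self.k_values))

    def validate(self) -> None:
        for g in self.graphs:
            if not np.array_equal(g, g.T):
                raise ValueError("sub-graph adjacency not symmetric")
            if np.trace(g) != 0:
                raise ValueError("sub-graph adjacency has nonzero diagonal")
            if not np.isin(g, (0, 1)).all():
                raise ValueError("sub-graph adjacency not binary")


def count_paths(hg: DrugHG, spec: MetaPathSpec) -> np.ndarray:
    """Count meta-path instances between every drug pair.

    For a 2-hop path D–A–D the count matrix is ``M_DA @ M_DA.T``; its diagonal
    entry i is the number of type-A attributes of drug i.  For D–P–P–D the
    chain is ``M_DP @ (M_PP + I) @ M_DP.T``: protein self-loops are included
    so that a drug's self-count dominates its target count and the PathSim
    denominator cannot vanish for target-bearing drugs.
    """
    if not spec.available_in(hg):
        raise MetaPathUnavailable(
            f"meta-path {spec.name} unavailable: missing attribute type "
            f"{spec.attribute_type!r}" + (" or PPI matrix" if spec.name == "DPPD" else ""))
    M = hg.incidence[spec.attribute_type].astype(np.int64)
    if spec.name == "DPPD":
        P = hg.ppi.astype(np.int64) + np.eye(hg.ppi.shape[0], dtype=np.int64)
        return M @ P @ M.T
    return M @ M.T


def pathsim(counts: np.ndarray) -> np.ndarray:
    """PathSim: s(i,j) = 2*c_ij / (c_ii + c_jj), 0 when the denominator is 0."""
    counts = np.asarray(counts)
    diag = np.diag(counts).astype(np.float64)
    denom = diag[:, None] + diag[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, 2.0 * counts / np.where(denom > 0, denom, 1.0), 0.0)
    return sim


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def default_topk(sim: np.ndarray) -> int:
    """Average neighbor count on the nonzero-similarity graph, floored at 1."""
    n = sim.shape[0]
    off = sim.copy()
    np.fill_diagonal(off, 0.0)
    nonzero = int((off > 0).sum())
    return max(1, _round_half_away(nonzero / n))


def neighbor_filter(sim: np.ndarray, k: int) -> np.ndarray:
    """Keep each drug's top-K nonzero-similarity neighbors, union-symmetrized.

    Ties are broken toward the smaller drug index; zero similarities are never
    selected even when fewer than K neighbors exist.  An edge survives if
    either endpoint selected the other.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    n = sim.shape[0]
    adj = np.zeros((n, n), dtype=np.int64)
    off = np.array(sim, dtype=float)
    np.fill_diagonal(off, 0.0)
    # stable argsort on -sim: equal similarities keep index order (smaller first)
    order = np.argsort(-off, axis=1, kind="stable")
    n_pos = (off > 0).sum(axis=1)
    for i in range(n):
        # positives occupy the sorted prefix; zeros are never selected
        picks = order[i, : min(k, n_pos[i])]
        adj[i, picks] = 1
    adj = np.maximum(adj, adj.T)
    np.fill_diagonal(adj, 0)
    return adj


def available_specs(hg: DrugHG, include_ppi: bool = True) -> list[MetaPathSpec]:
    """Constructible meta-paths in canonical order; DPPD dropped if excluded."""
    specs = []
    for name in CANONICAL_ORDER:
        if name == "DPPD" and not include_ppi:
            continue
        s = MetaPathSpec(name)
        if s.available_in(hg):
            specs.append(s)
    return specs


def build_subgraphs(
    hg: DrugHG,
    specs: list[MetaPathSpec] | None = None,
    k_overrides: dict | None = None,
    include_ppi: bool = True,
) -> SubGraphSet:
    """Full per-meta-path pipeline: counts → PathSim → top-K filter.

    ``k_overrides`` maps meta-path name to a fixed K; otherwise K defaults to
    the average number of connections under that meta-path.
    """
    if specs is None:
        specs = available_specs(hg, include_ppi=include_ppi)
    if not specs:
        raise ValueError("no meta-path specs to build sub-graphs from")
    graphs, names, ks = [], [], []
    for spec in specs:
        counts = count_paths(hg, spec)
        sim = pathsim(counts)
        k = (k_overrides or {}).get(spec.name) or default_topk(sim)
        graphs.append(neighbor_filter(sim, k))
        names.append(spec.name)
        ks.append(k)
    out = SubGraphSet(graphs, names, ks)
    out.validate()
    return out


def write_subgraphs(sgs: SubGraphSet, drug_ids: list, out_dir: str) -> None:
    """Serialize each sub-graph as an edge-list TSV plus a manifest."""
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    manifest = []
    for g, name, k in zip(sgs.graphs, sgs.names, sgs.k_values):
        path = os.path.join(out_dir, f"subgraph_{name}.tsv")
        iu, ju = np.triu_indices_from(g, k=1)
        n_edges = 0
        with open(path, "w", encoding="utf-8") as fh:
            for i, j in zip(iu, ju):
                if g[i, j]:
                    fh.write(f"{drug_ids[i]}\t{drug_ids[j]}\n")
                    n_edges += 1
        manifest.append({"metapath": name, "K": int(k), "edges": n_edges})
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
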