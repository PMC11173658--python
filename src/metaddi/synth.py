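"""Planted-cluster synthetic data with the structure the method assumes.

The generator emulates the shape of curated DDI-event datasets: a few hundred
drugs with per-type binary attribute profiles (chemical substructures, target
proteins, enzymes, transport pathways), a symmetric PPI graph over the target
proteins, and a labeled pair table over |E| event types with a long-tailed
event-frequency distribution.

Structure is planted through latent drug clusters: every attribute node is
owned by one cluster and drugs link to own-cluster attributes with
probability ``p_in`` versus ``p_out`` elsewhere, so meta-path similarity is
high within clusters.  The event label of a pair is a deterministic function
of the two drugs' clusters, flipped with probability ``label_noise`` — both
contrastive views therefore carry recoverable signal.  Event frequencies
follow a power-law-like tail controlled by ``tail_exponent``.

SMILES strings are random token strings (not chemically valid), exercising
the character-unigram fallback of the featurizer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .espf import espf_encode, espf_fit
from .hg import DrugHG, write_ddis, write_tables
from .pipeline import PairDataset

_SMILES_ALPHABET = list("CNOSPcnos123()=#[]+-")


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; defaults give a desk-scale planted-structure dataset."""

    n_drugs: int = 200
    n_clusters: int = 4
    attribute_counts: dict = field(default_factory=lambda: {"C": 60, "P": 40, "E": 20, "T": 20})
    p_in: float = 0.6
    p_out: float = 0.05
    ppi_density: float = 0.3
    n_events: int = 4
    n_pairs: int = 2000
    label_noise: float = 0.05
    tail_exponent: float = 1.0
    espf_max_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_drugs:
            raise ValueError("more clusters than drugs")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_events < 2:
            raise ValueError("need at least 2 event types")
        if not (0 <= self.label_noise <= 1):
            raise ValueError("label_noise must be in [0, 1]")


def _random_smiles(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 25))
    return "".join(rng.choice(_SMILES_ALPHABET, size=length))


def generate(cfg: SynthConfig) -> tuple[DrugHG, PairDataset, dict]:
    """Draw a (DrugHG, PairDataset, ground truth) triple; byte-deterministic.

    Ground truth contains the latent cluster assignment, the clean
    (pre-noise) labels and the cluster-pair -> event map, for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_drugs, cfg.n_clusters
    clusters = rng.integers(0, k, size=n)
    # guarantee every cluster is populated
    for c in range(k):
        if not (clusters == c).any():
            clusters[rng.integers(n)] = c

    drug_ids = [f"D{i:04d}" for i in range(n)]
    incidence, attr_ids = {}, {}
    for t, n_attr in cfg.attribute_counts.items():
        if n_attr <= 0:
            continue
        owners = np.arange(n_attr) % k
        probs = np.where(clusters[:, None] == owners[None, :], cfg.p_in, cfg.p_out)
        M = (rng.random((n, n_attr)) < probs).astype(np.int64)
        # no empty columns (attributes must survive a TSV round trip) and no
        # attribute-free drugs (they would be isolated in every sub-graph)
        for j in np.flatnonzero(M.sum(axis=0) == 0):
            members = np.flatnonzero(clusters == owners[j])
            M[rng.choice(members), j] = 1
        for i in np.flatnonzero(M.sum(axis=1) == 0):
            own = np.flatnonzero(owners == clusters[i])
            M[i, rng.choice(own)] = 1
        incidence[t] = M
        attr_ids[t] = [f"{t}{j:04d}" for j in range(n_attr)]

    ppi = None
    if "P" in incidence:
        n_p = incidence["P"].shape[1]
        owners = np.arange(n_p) % k
        same = owners[:, None] == owners[None, :]
        p_edge = np.where(same, cfg.ppi_density, cfg.ppi_density * 0.1)
        draw = rng.random((n_p, n_p))
        upper = np.triu(draw < p_edge, k=1).astype(np.int64)
        ppi = upper + upper.T

    smiles = {d: _random_smiles(rng) for d in drug_ids}
    vocab = espf_fit([smiles[d] for d in drug_ids], min_freq=2,
                     max_size=cfg.espf_max_size)
    X = np.zeros((n, vocab.size), dtype=np.int64)
    unparseable = []
    for i, d in enumerate(drug_ids):
        X[i], ok = espf_encode(smiles[d], vocab)
        if not ok:
            unparseable.append(d)

    hg = DrugHG(drug_ids=drug_ids, attr_ids=attr_ids, incidence=incidence,
                ppi=ppi, X=X, smiles=smiles, vocab=vocab, unparseable=unparseable)
    hg.validate()

    # ---- labels: event = f(cluster pair), long-tailed instance counts
    cluster_pairs = [(a, b) for a in range(k) for b in range(a, k)]
    event_of_cpair = {cp: idx % cfg.n_events for idx, cp in enumerate(cluster_pairs)}
    candidates: dict[int, list] = {e: [] for e in range(cfg.n_events)}
    for i in range(n):
        for j in range(i + 1, n):
            cp = tuple(sorted((clusters[i], clusters[j])))
            candidates[event_of_cpair[cp]].append((i, j))
    weights = np.array([(e + 1.0) ** (-cfg.tail_exponent) for e in range(cfg.n_events)])
    targets = np.maximum(1, np.round(cfg.n_pairs * weights / weights.sum())).astype(int)
    pairs, clean_labels = [], []
    for e in range(cfg.n_events):
        cand = candidates[e]
        if not cand:
            continue
        take = min(targets[e], len(cand))
        chosen = rng.choice(len(cand), size=take, replace=False)
        for ci in chosen:
            i, j = cand[ci]
            label = e
            clean_labels.append(e)
            if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
                others = [x for x in range(cfg.n_events) if x != e]
                label = int(rng.choice(others))
            pairs.append((drug_ids[i], drug_ids[j], label))

    dataset = PairDataset(pairs=pairs, n_events=cfg.n_events)
    truth = {"clusters": clusters, "clean_labels": np.array(clean_labels),
             "event_of_cluster_pair": event_of_cpair}
    return hg, dataset, truth


def write_fixture(hg: DrugHG, dataset: PairDataset, out_dir: str) -> None:
    """Emit the exact TSV formats the graph builder consumes."""
    os.makedirs(out_dir, exist_ok=True)
    write_tables(hg, out_dir)
    write_ddis(dataset.pairs, os.path.join(out_dir, "ddis.tsv"))
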