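"""End-to-end DDI event prediction: splits, training loop, metrics, ranking.

A labeled pair (i, j, event) is represented by concatenating both drugs'
embeddings from both contrastive views,  z_(i,j) = z_i^C || z_i^F || z_j^C ||
z_j^F  (length 4d), and classified by an MLP + softmax over |E| event types.
Because DDI labels are undirected while the concatenation is ordered, each
pair is presented in both orders during training and the two orders' softmax
outputs are averaged at evaluation time.

Three evaluation regimes are supported:
  Task 1 — split *instances* per event (every event present in every split);
  Task 2 — split *drugs*; test pairs have exactly one unseen drug;
  Task 3 — split *drugs*; test pairs have two unseen drugs.

Training optimizes  L = L_s + alpha (L_uc + L_sc)  with Adam, full-graph
encoding and one optimizer step per epoch; the supervised-contrastive term
is evaluated on a per-epoch random minibatch of pairs.  Augmentation is a
training-time regularizer only: evaluation always encodes the clean graphs.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, precision_score, recall_score)

from . import nn
from .augment import AugmentationConfig, build_augmented_set
from .encoder import (AVERAGE_VIEW, EncoderParams, encode_augmented_view,
                      encode_average_view, init_encoder_params,
                      transform_features)
from .hg import DrugHG
from .losses import (LossConfig, info_nce_views, prediction_loss,
                     supervised_contrastive, total_loss)
from .metapath import SubGraphSet, available_specs, build_subgraphs
from .nn import Adam, Tensor

logger = logging.getLogger(__name__)

SPLITS = ("train", "valid", "test")
DISCARD = "discard"

#: Dataset-style frequency-group bins: first bin closed, rest half-open (lo, hi].
FREQUENCY_BINS_SMALL = ((1, 10), (10, 50), (50, 100), (100, 300), (300, math.inf))


# --------------------------------------------------------------------- data
@dataclass
class PairDataset:
    """Labeled drug pairs with event ids and (optional) split assignments."""

    pairs: list                       # (drug_a, drug_b, event_id)
    n_events: int
    split_tags: list | None = None    # per pair: train/valid/test/discard
    drug_split: dict | None = None    # drug_id -> split (Tasks 2/3)

    def __post_init__(self):
        seen: dict = {}
        for a, b, e in self.pairs:
            if not (0 <= e < self.n_events):
                raise ValueError(f"event id {e} outside [0, {self.n_events})")
            key = frozenset((a, b))
            if key in seen and seen[key] != e:
                raise ValueError(f"pair {a}–{b} labeled with conflicting events")
            seen[key] = e

    @property
    def event_counts(self) -> np.ndarray:
        out = np.zeros(self.n_events, dtype=np.int64)
        for _, _, e in self.pairs:
            out[e] += 1
        return out

    def indices(self, split: str) -> list:
        if self.split_tags is None:
            raise ValueError("dataset has no split assignment")
        return [i for i, t in enumerate(self.split_tags) if t == split]

    def subset(self, split: str) -> list:
        return [self.pairs[i] for i in self.indices(split)]


def split_task1(dataset: PairDataset, ratios=(0.7, 0.1, 0.2), seed: int = 0) -> list:
    """Stratified instance split: per event, shuffle and cut 7:1:2.

    Events with fewer than 3 instances go wholly to train (warned), so no
    split receives an event the training set has never seen.
    """
    if not dataset.pairs:
        raise ValueError("cannot split an empty dataset")
    if not math.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    tags = [None] * len(dataset.pairs)
    by_event: dict = {}
    for i, (_, _, e) in enumerate(dataset.pairs):
        by_event.setdefault(e, []).append(i)
    for e in sorted(by_event):
        idx = np.array(by_event[e])
        rng.shuffle(idx)
        n = idx.size
        if n < 3:
            logger.warning("event %d has %d instances; all placed in train", e, n)
            for i in idx:
                tags[i] = "train"
            continue
        n_valid = int(np.floor(ratios[1] * n))
        n_test = int(np.floor(ratios[2] * n))
        for i in idx[: n - n_valid - n_test]:
            tags[i] = "train"
        for i in idx[n - n_valid - n_test: n - n_test]:
            tags[i] = "valid"
        for i in idx[n - n_test:]:
            tags[i] = "test"
    return tags


def split_task23(dataset: PairDataset, drug_ids: list, task: int,
                 ratios=(0.7, 0.1, 0.2), seed: int = 0) -> tuple[list, dict]:
    """Cold-start split: partition *drugs* 7:1:2, then derive pair tags.

    Task 2 test pairs have exactly one test drug (the other in train); Task 3
    test pairs have two test drugs.  Validation is analogous with validation
    drugs.  Pairs mixing splits in any other way are discarded (logged).
    """
    if task not in (2, 3):
        raise ValueError("task must be 2 or 3")
    rng = np.random.default_rng(seed)
    drugs = np.array(drug_ids, dtype=object)
    rng.shuffle(drugs)
    n = drugs.size
    n_valid = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_valid - n_test
    if min(n_train, n_valid, n_test) == 0:
        raise ValueError("drug split produced an empty partition; need more drugs")
    drug_split = {d: "train" for d in drugs[:n_train]}
    drug_split.update({d: "valid" for d in drugs[n_train:n_train + n_valid]})
    drug_split.update({d: "test" for d in drugs[n_train + n_valid:]})
    tags = []
    discarded = 0
    for a, b, _ in dataset.pairs:
        sa, sb = drug_split[a], drug_split[b]
        kinds = frozenset((sa, sb))
        if kinds == {"train"}:
            tags.append("train")
        elif task == 2 and kinds == {"train", "valid"}:
            tags.append("valid")
        elif task == 2 and kinds == {"train", "test"}:
            tags.append("test")
        elif task == 3 and kinds == {"valid"}:
            tags.append("valid")
        elif task == 3 and kinds == {"test"}:
            tags.append("test")
        else:
            tags.append(DISCARD)
            discarded += 1
    if discarded:
        logger.info("task %d split: discarded %d pairs mixing incompatible drug splits",
                    task, discarded)
    return tags, drug_split


def assert_no_leakage(dataset: PairDataset, drug_split: dict) -> None:
    """No test (or validation) drug may appear in any training pair."""
    for (a, b, _), tag in zip(dataset.pairs, dataset.split_tags):
        if tag == "train":
            if drug_split[a] != "train" or drug_split[b] != "train":
                raise AssertionError(f"cold-start leakage: training pair {a}–{b} "
                                     "contains a non-training drug")


# ------------------------------------------------------------------ MLP head
@dataclass
class MLPHead:
    """Feed-forward classifier from the 4d pair representation to |E| logits."""

    weights: list            # Tensor (out, in) per layer
    biases: list             # Tensor (out,) per layer
    dropout: float = 0.0

    def tensors(self) -> list[Tensor]:
        return [*self.weights, *self.biases]

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ W.T + b
            if i < len(self.weights) - 1:
                x = nn.relu(x)
                if self.dropout > 0 and rng is not None:
                    keep = (rng.random(x.shape) >= self.dropout) / (1 - self.dropout)
                    x = x * Tensor(keep)
        return x


def init_mlp_head(rng: np.random.Generator, d: int, n_events: int,
                  hidden: tuple = (64,), dropout: float = 0.0) -> MLPHead:
    sizes = [4 * d, *hidden, n_events]
    weights = [nn.xavier_uniform(rng, (sizes[i + 1], sizes[i]))
               for i in range(len(sizes) - 1)]
    biases = [nn.parameter(np.zeros(sizes[i + 1])) for i in range(len(sizes) - 1)]
    return MLPHead(weights, biases, dropout=dropout)


def pair_embed(z_c, z_f, i, j) -> Tensor:
    """Eq-style ordered concatenation z_i^C || z_i^F || z_j^C || z_j^F."""
    return pair_matrix(z_c, z_f, [i], [j]).reshape(-1)


def pair_matrix(z_c, z_f, idx_a, idx_b) -> Tensor:
    z_c, z_f = nn.as_tensor(z_c), nn.as_tensor(z_f)
    idx_a = np.asarray(idx_a, dtype=np.intp)
    idx_b = np.asarray(idx_b, dtype=np.intp)
    return nn.concat([z_c.take_rows(idx_a), z_f.take_rows(idx_a),
                      z_c.take_rows(idx_b), z_f.take_rows(idx_b)], axis=1)


def predict_pairs(pair_vectors, head: MLPHead) -> Tensor:
    """Softmax event probabilities for a batch of pair vectors."""
    logits = head.forward(nn.as_tensor(pair_vectors))
    return nn.softmax(logits, axis=1)


# ----------------------------------------------------------------- training
@dataclass
class TrainConfig:
    """Hyper-parameters of the full model.

    Defaults follow the documented settings: 8 attention heads, temperature
    0.05, balance coefficient 0.1, Adam at 1e-3, Xavier initialization.
    """

    d: int = 32
    n_heads: int = 8
    lr: float = 1e-2
    epochs: int = 200
    batch_size: int = 256
    seed: int = 0
    hidden: tuple = (64,)
    dropout: float = 0.0
    activation: str = "elu"
    include_ppi: bool = True
    k_overrides: dict | None = None
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    loss: LossConfig = field(default_factory=LossConfig)


@dataclass
class TrainedModel:
    """Trained parameter set plus everything needed to embed and predict."""

    encoder: EncoderParams
    head: MLPHead
    clean_subgraphs: SubGraphSet
    config: TrainConfig
    drug_ids: list
    n_events: int
    X: np.ndarray
    loss_log: list = field(default_factory=list)

    def drug_index(self) -> dict:
        return {d: i for i, d in enumerate(self.drug_ids)}

    def embeddings(self) -> tuple[np.ndarray, np.ndarray]:
        """Clean-view embeddings (Z_C, Z_F); inference never augments."""
        h = transform_features(self.X, self.encoder)
        z_c = encode_average_view(self.clean_subgraphs, h, self.encoder)
        z_f = encode_augmented_view(self.clean_subgraphs, h, self.encoder)
        return z_c.data, z_f.data

    def predict_proba(self, pairs: list) -> np.ndarray:
        """Order-averaged event probabilities for (drug_a, drug_b) pairs."""
        index = self.drug_index()
        ia = np.array([index[a] for a, b, *_ in pairs])
        ib = np.array([index[b] for a, b, *_ in pairs])
        z_c, z_f = self.embeddings()
        p_ab = predict_pairs(pair_matrix(z_c, z_f, ia, ib), self.head).data
        p_ba = predict_pairs(pair_matrix(z_c, z_f, ib, ia), self.head).data
        return 0.5 * (p_ab + p_ba)


def train(hg: DrugHG, dataset: PairDataset, cfg: TrainConfig) -> TrainedModel:
    """Fit the full model; deterministic given ``cfg.seed``.

    Per epoch: rebuild the corrupted sub-graph set, encode both views (the
    average view always from the clean sub-graphs), take one Adam step on the
    combined loss over all training pairs in both orders.  Raises on a
    non-finite loss.
    """
    if dataset.split_tags is None:
        raise ValueError("dataset must carry split assignments before training")
    rng = np.random.default_rng(cfg.seed)
    index = {d: i for i, d in enumerate(hg.drug_ids)}
    specs = available_specs(hg, include_ppi=cfg.include_ppi)
    clean = build_subgraphs(hg, specs, k_overrides=cfg.k_overrides)
    k_values = dict(zip(clean.names, clean.k_values))

    params = init_encoder_params(rng, hg.X.shape[1], cfg.d, cfg.n_heads,
                                 clean.names, activation=cfg.activation)
    head = init_mlp_head(rng, cfg.d, dataset.n_events, hidden=cfg.hidden,
                         dropout=cfg.dropout)
    opt = Adam([*params.tensors(), *head.tensors()], lr=cfg.lr)

    train_pairs = dataset.subset("train")
    if not train_pairs:
        raise ValueError("no training pairs")
    # both orders per labeled pair (the concatenation is order-dependent)
    ia = np.array([index[a] for a, _, _ in train_pairs] +
                  [index[b] for _, b, _ in train_pairs])
    ib = np.array([index[b] for _, b, _ in train_pairs] +
                  [index[a] for a, _, _ in train_pairs])
    labels = np.array([e for _, _, e in train_pairs] * 2)

    aug = AugmentationConfig(af=cfg.augmentation.af, ae=cfg.augmentation.ae,
                             ag=cfg.augmentation.ag, mode=cfg.augmentation.mode,
                             seed=cfg.seed)
    loss_log = []
    for epoch in range(cfg.epochs):
        if aug.mode == "none":
            corrupted = clean
        else:
            corrupted = build_augmented_set(hg, specs, aug, epoch, k_values)
        h = transform_features(hg.X, params)
        z_c = encode_average_view(clean, h, params)
        z_f = encode_augmented_view(corrupted, h, params)

        vecs = pair_matrix(z_c, z_f, ia, ib)
        probs = predict_pairs(vecs, head)
        l_s = prediction_loss(probs, labels)
        l_uc = info_nce_views(z_c, z_f, cfg.loss.tau)
        if len(labels) > cfg.batch_size:
            batch = rng.choice(len(labels), size=cfg.batch_size, replace=False)
        else:
            batch = np.arange(len(labels))
        l_sc = supervised_contrastive(vecs.take_rows(batch), labels[batch],
                                      cfg.loss.tau)
        loss = total_loss(l_s, l_uc, l_sc, cfg.loss.alpha)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: "
                f"L_s={l_s.item():.4g} L_uc={l_uc.item():.4g} L_sc={l_sc.item():.4g}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss_log.append({"epoch": epoch, "L_s": l_s.item(), "L_uc": l_uc.item(),
                         "L_sc": l_sc.item(), "L": loss.item()})
    return TrainedModel(encoder=params, head=head, clean_subgraphs=clean,
                        config=cfg, drug_ids=list(hg.drug_ids),
                        n_events=dataset.n_events, X=hg.X, loss_log=loss_log)


# ------------------------------------------------------------------ metrics
def evaluate(probs: np.ndarray, labels, n_events: int,
             event_counts=None, bins=None) -> dict:
    """Multi-class metric report.

    ACC is overall accuracy; AUPR is micro-averaged over one-vs-rest
    binarization; macro-F1/recall/precision average over the event classes
    present in ``labels`` (absent classes are excluded, noted in the report).
    ``event_counts`` + ``bins`` add per-frequency-group macro-F1.
    """
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    preds = probs.argmax(axis=1)
    present = np.unique(labels)
    onehot = np.zeros_like(probs)
    onehot[np.arange(labels.size), labels] = 1.0
    report = {
        "acc": float(accuracy_score(labels, preds)),
        "aupr": float(average_precision_score(onehot, probs, average="micro")),
        "macro_f1": float(f1_score(labels, preds, labels=present,
                                   average="macro", zero_division=0)),
        "macro_rec": float(recall_score(labels, preds, labels=present,
                                        average="macro", zero_division=0)),
        "macro_pre": float(precision_score(labels, preds, labels=present,
                                           average="macro", zero_division=0)),
        "n": int(labels.size),
        "events_scored": [int(e) for e in present],
        "events_absent": [int(e) for e in range(n_events) if e not in set(present)],
    }
    per_event = {}
    for e in present:
        per_event[int(e)] = {
            "f1": float(f1_score(labels, preds, labels=[e], average="macro",
                                 zero_division=0)),
            "support": int((labels == e).sum()),
        }
    report["per_event"] = per_event
    if event_counts is not None and bins is not None:
        groups = group_events(np.asarray(event_counts), bins)
        per_group = {}
        for gi in range(len(bins)):
            evs = [e for e in present if groups[e] == gi]
            if not evs:
                continue
            per_group[str(bins[gi])] = {
                "macro_f1": float(f1_score(labels, preds, labels=evs,
                                           average="macro", zero_division=0)),
                "events": [int(e) for e in evs],
            }
        report["per_group"] = per_group
    return report


def group_events(event_counts: np.ndarray, bins=FREQUENCY_BINS_SMALL) -> np.ndarray:
    """Assign each event to a frequency bin.

    The first bin is closed, later bins are half-open (lo, hi]; a count of 10
    with the default edges lands in the first bin, 11 in the second.  Bins
    must be non-overlapping and cover every observed count.
    """
    bins = list(bins)
    for (lo1, hi1), (lo2, hi2) in zip(bins, bins[1:]):
        if lo2 < hi1:
            raise ValueError("overlapping frequency bins")
    out = np.full(len(event_counts), -1, dtype=np.int64)
    for e, c in enumerate(event_counts):
        for gi, (lo, hi) in enumerate(bins):
            if (gi == 0 and lo <= c <= hi) or (gi > 0 and lo < c <= hi):
                out[e] = gi
                break
        else:
            raise ValueError(f"event count {c} not covered by any bin")
    return out


def majority_baseline(train_labels, test_labels, n_events: int) -> dict:
    """Metric report of the constant predictor using training frequencies."""
    train_labels = np.asarray(train_labels)
    freqs = np.bincount(train_labels, minlength=n_events).astype(float)
    freqs /= freqs.sum()
    probs = np.tile(freqs, (len(test_labels), 1))
    return evaluate(probs, test_labels, n_events)


# ------------------------------------------------------------------ ranking
def rank_novel_pairs(model: TrainedModel, known_pairs: list, top_n: int = 10,
                     events_of_interest: list | None = None) -> dict:
    """Per-event top-N unlabeled pairs by order-averaged predicted probability."""
    known = {frozenset((a, b)) for a, b, *_ in known_pairs}
    candidates = []
    ids = model.drug_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if frozenset((ids[i], ids[j])) not in known:
                candidates.append((ids[i], ids[j]))
    if not candidates:
        return {}
    probs = model.predict_proba([(a, b) for a, b in candidates])
    events = events_of_interest if events_of_interest is not None \
        else list(range(model.n_events))
    out = {}
    for e in events:
        order = np.argsort(-probs[:, e], kind="stable")[:top_n]
        out[int(e)] = [(candidates[i][0], candidates[i][1], float(probs[i, e]))
                       for i in order]
    return out


# -------------------------------------------------------------- persistence
def save_model(model: TrainedModel, run_dir: str) -> None:
    os.makedirs(run_dir, exist_ok=True)
    state, meta = {}, {
        "d": model.config.d, "n_heads": model.config.n_heads,
        "hidden": list(model.config.hidden), "n_events": model.n_events,
        "activation": model.config.activation,
        "drug_ids": model.drug_ids,
        "graph_names": model.clean_subgraphs.names,
        "k_values": [int(k) for k in model.clean_subgraphs.k_values],
    }
    enc = model.encoder
    state.update({"W": enc.W.data, "b": enc.b.data, "W1": enc.W1.data,
                  "b1": enc.b1.data, "q1": enc.q1.data, "X": model.X})
    for name, gp in enc.graph_params.items():
        for k, (a, W) in enumerate(zip(gp.a, gp.W)):
            state[f"g:{name}:a{k}"] = a.data
            state[f"g:{name}:W{k}"] = W.data
        state[f"g:{name}:b"] = gp.b.data
        state[f"g:{name}:slope"] = gp.prelu_slope.data
    for i, (W, b) in enumerate(zip(model.head.weights, model.head.biases)):
        state[f"head:W{i}"] = W.data
        state[f"head:b{i}"] = b.data
    for gi, g in enumerate(model.clean_subgraphs.graphs):
        state[f"sg:{gi}"] = g
    np.savez(os.path.join(run_dir, "model.npz"), **state)
    with open(os.path.join(run_dir, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    with open(os.path.join(run_dir, "losses.jsonl"), "w", encoding="utf-8") as fh:
        for rec in model.loss_log:
            fh.write(json.dumps(rec) + "\n")


def load_model(run_dir: str) -> TrainedModel:
    with open(os.path.join(run_dir, "meta.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    state = np.load(os.path.join(run_dir, "model.npz"), allow_pickle=False)
    from .encoder import GraphAttentionParams
    gp = {}
    for name in [AVERAGE_VIEW, *meta["graph_names"]]:
        a = [nn.parameter(state[f"g:{name}:a{k}"]) for k in range(meta["n_heads"])]
        W = [nn.parameter(state[f"g:{name}:W{k}"]) for k in range(meta["n_heads"])]
        gp[name] = GraphAttentionParams(a=a, W=W,
                                        b=nn.parameter(state[f"g:{name}:b"]),
                                        prelu_slope=nn.parameter(state[f"g:{name}:slope"]))
    enc = EncoderParams(W=nn.parameter(state["W"]), b=nn.parameter(state["b"]),
                        graph_params=gp, W1=nn.parameter(state["W1"]),
                        b1=nn.parameter(state["b1"]), q1=nn.parameter(state["q1"]),
                        d=meta["d"], n_heads=meta["n_heads"],
                        activation=meta["activation"])
    n_layers = len([k for k in state.files if k.startswith("head:W")])
    head = MLPHead(weights=[nn.parameter(state[f"head:W{i}"]) for i in range(n_layers)],
                   biases=[nn.parameter(state[f"head:b{i}"]) for i in range(n_layers)])
    graphs = [state[f"sg:{gi}"] for gi in range(len(meta["graph_names"]))]
    clean = SubGraphSet(graphs=graphs, names=meta["graph_names"],
                        k_values=meta["k_values"])
    cfg = TrainConfig(d=meta["d"], n_heads=meta["n_heads"],
                      hidden=tuple(meta["hidden"]), activation=meta["activation"])
    return TrainedModel(encoder=enc, head=head, clean_subgraphs=clean, config=cfg,
                        drug_ids=list(meta["drug_ids"]), n_events=meta["n_events"],
                        X=state["X"])
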