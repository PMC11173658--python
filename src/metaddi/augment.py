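"""Three-level stochastic masking for the augmented contrastive view.

Level 1 masks attribute *nodes* (whole incidence columns): removing a shared
substructure deletes every meta-path instance through it.  Level 2 masks
edges of the rebuilt per-meta-path sub-graphs.  Level 3 drops, with
probability ``ag``, exactly one uniformly chosen sub-graph.  Perturbation
intensity increases with level; the clean inputs are never mutated in place.

Per epoch, the corrupted set is produced by
feature-mask → rebuild sub-graphs → sub-graph drop → edge-mask,
driven by a random stream derived from (seed, epoch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hg import DrugHG
from .metapath import MetaPathSpec, SubGraphSet, build_subgraphs

logger = logging.getLogger(__name__)

MODES = ("full", "none", "f", "e", "g")


@dataclass(frozen=True)
class AugmentationConfig:
    """Masking ratios for the three augmentation levels.

    ``af``/``ae`` are fractions of attribute nodes / sub-graph edges removed;
    ``ag`` is the per-epoch probability of dropping one sub-graph.  ``mode``
    selects which levels are active: ``full`` (all), ``none``, or exactly one
    of ``f``/``e``/``g``.
    """

    af: float = 0.2
    ae: float = 0.3
    ag: float = 0.2
    mode: str = "full"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.af < 1 and 0 <= self.ae < 1):
            raise ValueError("af and ae must be in [0, 1)")
        if not (0 <= self.ag <= 1):
            raise ValueError("ag must be in [0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def rng_for_epoch(self, epoch: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, epoch)))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def mask_features(hg: DrugHG, af: float, rng: np.random.Generator) -> DrugHG:
    """Zero ``round(af * n)`` attribute columns per type, chosen uniformly.

    PPI rows/columns of removed target proteins are zeroed as well, so no
    path may pass through a masked node.  Never removes all nodes of a type.
    The drug feature matrix X is untouched.
    """
    if not (0 <= af < 1):
        raise ValueError("af must be in [0, 1)")
    incidence = {t: M.copy() for t, M in hg.incidence.items()}
    ppi = hg.ppi.copy() if hg.ppi is not None else None
    for t in sorted(incidence):
        n = incidence[t].shape[1]
        if n == 0:
            continue
        n_mask = _round_half_away(af * n)
        if n_mask >= n:
            logger.warning("feature mask would remove all %s nodes; capping at %d", t, n - 1)
            n_mask = n - 1
        if n_mask == 0:
            continue
        cols = rng.choice(n, size=n_mask, replace=False)
        incidence[t][:, cols] = 0
        if t == "P" and ppi is not None:
            ppi[cols, :] = 0
            ppi[:, cols] = 0
    return DrugHG(drug_ids=hg.drug_ids, attr_ids=hg.attr_ids, incidence=incidence,
                  ppi=ppi, X=hg.X, smiles=hg.smiles, vocab=hg.vocab,
                  unparseable=hg.unparseable)


def mask_edges(sgs: SubGraphSet, ae: float, rng: np.random.Generator) -> SubGraphSet:
    """Remove exactly ``round(ae * m)`` unordered edges per sub-graph."""
    if not (0 <= ae < 1):
        raise ValueError("ae must be in [0, 1)")
    out = sgs.copy()
    for g in out.graphs:
        iu, ju = np.nonzero(np.triu(g, k=1))
        m = iu.size
        n_mask = _round_half_away(ae * m)
        if n_mask == 0:
            continue
        drop = rng.choice(m, size=n_mask, replace=False)
        g[iu[drop], ju[drop]] = 0
        g[ju[drop], iu[drop]] = 0
    return out


def mask_subgraph(sgs: SubGraphSet, ag: float, rng: np.random.Generator) -> SubGraphSet:
    """With probability ``ag``, drop one uniformly chosen sub-graph."""
    if not (0 <= ag <= 1):
        raise ValueError("ag must be in [0, 1]")
    out = sgs.copy()
    if ag == 0 or rng.random() >= ag:
        return out
    if len(out) <= 1:
        logger.warning("sub-graph drop sampled but only one sub-graph present; skipping")
        return out
    victim = int(rng.integers(len(out)))
    del out.graphs[victim], out.names[victim], out.k_values[victim]
    return out


def build_augmented_set(
    hg: DrugHG,
    specs: list[MetaPathSpec],
    cfg: AugmentationConfig,
    epoch: int,
    k_values: dict | None = None,
) -> SubGraphSet:
    """Produce the corrupted sub-graph set for one training epoch.

    ``k_values`` fixes the top-K per meta-path (normally taken from the clean
    graph) so K stays stable while the masked graph changes.
    """
    rng = cfg.rng_for_epoch(epoch)
    do_f = cfg.mode in ("full", "f")
    do_e = cfg.mode in ("full", "e")
    do_g = cfg.mode in ("full", "g")
    hg_masked = mask_features(hg, cfg.af, rng) if (do_f and cfg.af > 0) else hg
    sgs = build_subgraphs(hg_masked, specs, k_overrides=k_values)
    if do_g:
        sgs = mask_subgraph(sgs, cfg.ag, rng)
    if do_e and cfg.ae > 0:
        sgs = mask_edges(sgs, cfg.ae, rng)
    return sgs
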