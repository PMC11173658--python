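# Methods

This note documents the model implemented by `metaddi`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Graph construction

The drug heterogeneous graph has drug nodes plus up to four attribute node
sets (chemical substructure C, target protein P, enzyme E, transport pathway
T) with binary incidence relations, and a symmetric zero-diagonal PPI matrix
over the target proteins.  Datasets may lack E or T tables; every downstream
stage restricts itself to the meta-paths that are constructible.  The protein
universe is restricted to drug targets: a PPI between two never-targeted
proteins can never appear on a D–P–P–D path, so dropping it changes no path
count while keeping matrices small.

Attribute and protein column order is first appearance in the input file —
matrices are a pure function of file content.  Tables are re-serialized
attribute-major so a write/reload cycle reproduces matrices exactly.

Drug features are binary substructure fingerprints from a byte-pair-style
vocabulary over SMILES: starting from atom/bond tokens (two-letter atoms and
bracket atoms kept whole), the most frequent adjacent token pair is merged
while its corpus count ≥ `min_freq` (default 2), up to `max_size` tokens
(default 2048); ties break lexicographically.  Encoding greedily matches the
longest vocabulary token.  SMILES that RDKit cannot parse are flagged and
fall back to character-unigram indicators rather than excluding the drug —
cold-start tasks need every drug to keep a feature row.  The exact vocabulary
hyper-parameters are exposed in configuration, not asserted; a precomputed
feature table can be supplied instead.

## Meta-paths and PathSim

Path-instance counts are incidence-chain products: `M_DA·M_DAᵀ` for 2-hop
paths, and `M_DP·(M_PP + I)·M_DPᵀ` for D–P–P–D.  The identity term adds
protein self-loops for this chain only: without it, a drug's self-count under
strict PPI chains can be zero while its cross-count is positive, making the
PathSim denominator vanish.  With it, `s(i,i) = 1` for every target-bearing
drug, at the cost that DPPD counts subsume shared-target paths.

PathSim is `s(i,j) = 2 c_ij / (c_ii + c_jj)`, defined as 0 when the
denominator is 0.  Per drug, the K most similar neighbors with *nonzero*
similarity are kept (loose neighbors are the thing being removed, so zeros
are never promoted even when fewer than K candidates exist); ties break
toward the smaller drug index.  Selection is per-row and then
union-symmetrized — an undirected edge survives if either endpoint selected
the other — because the encoder consumes undirected graphs.  K defaults to
the average connection count of the nonzero-similarity graph
(`round(#nonzero off-diagonal / |D|)`, half away from zero, floored at 1);
whether that average should be taken before or after zero-filtering is
ambiguous, so the computed default can be overridden per meta-path.

## Augmentation

Three masking levels, increasing in perturbation radius, produce the
corrupted sub-graph set each epoch:

1. **feature** — per attribute type, `round(a_f · n)` attribute *nodes*
   (incidence columns) are zeroed; PPI rows of removed targets are zeroed
   too.  Masking a node deletes every path through it, which is the intent:
   "features" here are graph features, not entries of the fingerprint matrix.
2. **sub-graph** — with probability `a_g`, exactly one uniformly chosen
   sub-graph is dropped (never below one graph).
3. **edge** — per surviving sub-graph, `round(a_e · m)` unordered edges are
   removed.

Counts round half away from zero and never remove 100% of anything.  The drop
decision is taken before edge masking so no work is spent corrupting a graph
about to be discarded; the output distribution is unchanged.  Sub-graphs are
*rebuilt* on the feature-masked graph each epoch, with K frozen from the
clean graph so neighborhood sizes stay stable across epochs; a flag allows
reusing clean sub-graphs instead.  All masking is driven by a stream derived
from (seed, epoch) and never mutates the caller's graphs.  Defaults
(a_f, a_e, a_g) = (0.2, 0.3, 0.2).

## Encoder

A shared feature transform `h_i = σ(W x_i + b)` (σ = ELU; unspecified
upstream, chosen for smoothness and configurable) feeds independent
multi-head attention modules per graph: the average view plus one per
meta-path.  Per head, pair scores are `LeakyReLU(aᵀ[h_i ‖ h_j])`
(slope 0.2), softmax-normalized over the neighborhood of i, aggregated as
`PReLU(Σ_j α_ij W_k h_j + b)` with a per-graph learnable PReLU slope and a
per-graph bias shared across heads; head outputs (dimension d/H) are
concatenated back to d.  Self-loops are always added so isolated drugs —
common in masked graphs and in cold-start settings — still produce
embeddings.  The aggregation uses neighbor embeddings `h_j`; a
`self_aggregate` switch reproduces the degenerate self-only variant for
comparison.

The average view attends over the *support* of the mean adjacency; the
fractional edge weights are not multiplied into attention (attention
re-learns edge importance), with a `use_edge_weights` flag to do so.

Semantic attention scores each sub-graph by
`e_P = q₁ᵀ · mean_i tanh(W₁ z_i^P + b₁)`, softmax-normalizes across the
(possibly shrunken) sub-graph set, and returns the weighted sum.  Dropping a
sub-graph automatically re-normalizes the weights over the survivors.

All parameters use Xavier-uniform initialization.

## Objectives

Similarity is cosine with temperature τ throughout (the standard choice for
InfoNCE/SupCon).  The cross-view loss treats the same drug in the other view
as the positive; denominators run over all |D| candidates of the other view
(positive included), and the two directions are averaged with the 1/(2|D|)
factor.  The supervised contrastive loss over a batch of pair embeddings
excludes the anchor from both its positive set and its denominator —
including it would bound the loss trivially — and anchors without positives
are excluded from the outer mean.  Prediction loss is batch-mean
cross-entropy with probabilities clipped at 1e-12.  The total is
`L = L_s + α (L_uc + L_sc)`; defaults τ = 0.05, α = 0.1.

## Training regime

The graphs are small enough to encode whole, so training takes **one Adam
step per epoch** on the full training set: `L_s` over all training pairs in
both orders, `L_uc` over all drugs, and `L_sc` over a fresh random minibatch
of pairs (default 256 — the supervised term is quadratic in batch size).
Because one epoch equals one update, the default learning rate is 1e-2; the
more conventional 1e-3 demonstrably underfits within a few hundred updates
at this scale.  No divergence was observed at 1e-2 in any configuration; a
non-finite loss aborts with diagnostics.

Pairs are presented in both orders during training and order-averaged at
prediction time, since the pair representation is ordered but DDI labels are
not.  Augmentation is a training-time regularizer only: inference always
encodes the clean sub-graph set for both views.

## Synthetic data

The generator plants recoverable structure: drugs belong to latent clusters,
attribute nodes are owned by clusters, and drug–attribute edges appear with
probability `p_in` (own cluster) versus `p_out`; PPIs are denser within
cluster-owned target sets (cross-cluster density is one tenth of
`ppi_density`).  Pair labels are a deterministic function of the unordered
cluster pair, flipped to a random other event with probability
`label_noise`; per-event instance counts follow `rank^(-tail_exponent)`, so
the label histogram is long-tailed like real DDI-event data.  Defaults
(200 drugs, 4 clusters, 4 events, p_in = 0.6, p_out = 0.05, noise = 0.05,
2000 pairs) are the conditions all learning tests use.

What this does *not* emulate: chemically valid SMILES (the generated strings
are random tokens, deliberately exercising the unigram fallback), realistic
attribute co-occurrence marginals, or the 37k–320k-pair scale of curated
datasets.  Passing the learning tests shows the pipeline can extract planted
meta-path signal end to end; it does not certify performance on real
DrugBank-derived data.

## Scale and observations

Tests and the acceptance script run at desk scale on one CPU: 200 drugs,
200 epochs (≈ half a minute), 500 epochs for the 50-pair capacity check.
Two empirical observations worth knowing:

* On the planted fixture the **un-augmented** (noMask) variant outperforms
  the fully augmented model (macro-F1 ≈ 0.88 vs ≈ 0.58 across seeds).  With
  only 200 full-batch updates, per-epoch graph corruption mostly slows
  convergence; augmentation earns its keep in many-update, larger-data
  regimes where overfitting is the binding constraint.  The ablation test
  reports this comparison without gating on its direction.
* Macro scores sit far below accuracy whenever the label tail is thin — the
  same pattern real DDI-event benchmarks show.

## Limitations

Single attention layer per graph (no stacking); no edge features or weighted
sub-graphs; no hard-negative mining; the supervised contrastive positives are
batch-wide, not dataset-wide; evaluation metrics exclude event classes absent
from the test split rather than scoring them zero.
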