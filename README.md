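# metaddi

Multi-class drug–drug interaction (DDI) **event** prediction with meta-path
heterogeneous graph contrastive learning.

Combining drugs can change what each drug does — metabolism may decrease,
serum concentration may rise, adverse-effect risk may grow.  Predicting *which*
interaction event a drug pair produces is a multi-class problem over dozens of
event types with a heavily long-tailed label distribution.  `metaddi` is for
computational drug-safety researchers who have per-drug attribute tables
(chemical substructures, target proteins, enzymes, transport pathways), a
protein–protein interaction (PPI) edge list and a labeled DDI table, and want
a tested, CPU-friendly implementation of the full method: graph construction,
meta-path similarity, contrastive training and cold-start evaluation.

## Method

Drugs and their attributes form a heterogeneous graph with node types
D (drug), C (substructure), P (target protein), E (enzyme), T (pathway) and
the relations D–C, D–P, D–E, D–T, P–P.  Five meta-paths connect drugs through
shared context: DCD, DPD, DED, DTD and the 3-hop DPPD (targets that interact).
For each meta-path, instance counts `p_ij` give the PathSim similarity

```
s(i, j) = 2 p_ij / (p_ii + p_jj)
```

and each drug keeps its top-K most similar neighbors (K defaults to the
average connection count under that meta-path), yielding one binary drug–drug
sub-graph per meta-path.

Two contrastive views are encoded with multi-head graph attention over a
shared feature transform `h_i = σ(W x_i + b)` of binary substructure
fingerprints (a BPE-style frequent-substructure vocabulary over SMILES):

* **average view** `z^C` — attention over the support of the *mean* of all
  clean sub-graph adjacencies ("are these drugs connected at all?");
* **augmented view** `z^F` — each sub-graph is encoded separately after three
  levels of stochastic masking (attribute nodes, sub-graph edges, whole
  sub-graphs), then fused with a learned semantic softmax over meta-paths
  ("how do they connect?").

Training minimizes `L = L_s + α (L_uc + L_sc)`: cross-entropy on the event
label of the pair representation `z_(i,j) = z_i^C ‖ z_i^F ‖ z_j^C ‖ z_j^F`
(MLP + softmax), a symmetric cross-view InfoNCE loss `L_uc`, and a supervised
contrastive loss `L_sc` whose positives are same-event pairs in the batch.
Defaults: 8 attention heads, temperature τ = 0.05, balance α = 0.1, Adam.

Evaluation covers three regimes — Task 1 (instance split, stratified per
event, 7:1:2), Task 2 (one test drug unseen in training) and Task 3 (both
unseen) — with accuracy, micro-averaged AUPR, macro-F1/recall/precision and
per-frequency-group reporting.

## Worked example

```python
import numpy as np
from metaddi import (SynthConfig, generate, split_task1, TrainConfig, train,
                     evaluate, majority_baseline)

cfg = SynthConfig(n_drugs=200, n_clusters=4, n_events=4, p_in=0.6,
                  p_out=0.05, label_noise=0.05, seed=7)
hg, dataset, truth = generate(cfg)          # planted-cluster synthetic data
dataset.split_tags = split_task1(dataset, seed=7)

model = train(hg, dataset, TrainConfig(d=32, n_heads=8, epochs=200, seed=7))
test = dataset.subset("test")
labels = [e for _, _, e in test]
report = evaluate(model.predict_proba(test), labels, dataset.n_events)
base = majority_baseline([e for _, _, e in dataset.subset("train")],
                         labels, dataset.n_events)
print(f"acc={report['acc']:.3f} aupr={report['aupr']:.3f} "
      f"macro_f1={report['macro_f1']:.3f} baseline_f1={base['macro_f1']:.3f}")
```

Output:

```
acc=0.647 aupr=0.652 macro_f1=0.376 baseline_f1=0.158
```

The model recovers enough of the planted cluster structure to reach 2.4× the
macro-F1 of a majority-class predictor on the 20% hold-out; AUPR is the
micro-averaged area under the one-vs-rest precision–recall curves.  Ordered
event frequencies in the synthetic set are long-tailed (926/480/341/253), so
macro scores are much lower than accuracy — exactly the regime DDI-event data
live in.

The same flow is available from the shell:

```bash
metaddi simulate --seed 7 --out fixture/
metaddi build-graph --drugs fixture/drugs.tsv --chem fixture/drug_attr_C.tsv \
    --target fixture/drug_attr_P.tsv --enzyme fixture/drug_attr_E.tsv \
    --pathway fixture/drug_attr_T.tsv --ppi fixture/ppi.tsv --out graph/
metaddi train --graph graph/ --ddis fixture/ddis.tsv --task 1 --seed 7 --out run/
metaddi evaluate --run run/ --split test
metaddi predict --run run/ --top-n 10
```

See `examples/` for narrative scripts, one per capability.

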