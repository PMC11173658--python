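import numpy as np
import pytest

from metaddi.hg import DrugHG


@pytest.fixture
def tiny_hg():
    """Two drugs sharing substructure c2; targets p1/p2 linked by one PPI."""
    return DrugHG(
        drug_ids=["d1", "d2"],
        attr_ids={"C": ["c1", "c2"], "P": ["p1", "p2"]},
        incidence={
            "C": np.array([[1, 1], [0, 1]]),
            "P": np.array([[1, 0], [0, 1]]),
        },
        ppi=np.array([[0, 1], [1, 0]]),
        X=np.eye(2, dtype=np.int64),
    )


def random_hg(rng, n_drugs=8, types=("C", "P", "E"), max_attrs=6, edge_p=0.35,
              ppi_p=0.3):
    """Random small heterogeneous graph for oracle comparisons."""
    attr_ids, incidence = {}, {}
    for t in types:
        n_attr = int(rng.integers(1, max_attrs + 1))
        attr_ids[t] = [f"{t.lower()}{k}" for k in range(n_attr)]
        incidence[t] = (rng.random((n_drugs, n_attr)) < edge_p).astype(np.int64)
    ppi = None
    if "P" in types:
        n_p = len(attr_ids["P"])
        upper = np.triu((rng.random((n_p, n_p)) < ppi_p), k=1).astype(np.int64)
        ppi = upper + upper.T
    return DrugHG(
        drug_ids=[f"d{i}" for i in range(n_drugs)],
        attr_ids=attr_ids,
        incidence=incidence,
        ppi=ppi,
        X=np.eye(n_drugs, dtype=np.int64),
    )
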