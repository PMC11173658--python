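"""Drug heterogeneous graph construction from flat TSV tables.

The graph has five node types — drugs (D), chemical substructures (C), target
proteins (P), enzymes (E) and transport pathways (T) — connected by binary
drug–attribute incidence relations plus a symmetric protein–protein
interaction (PPI) relation.  Enzyme and pathway tables are optional: datasets
without a given attribute simply lack the corresponding meta-paths downstream.

All column orderings are a pure function of file content (first appearance),
so rebuilding from the same files yields byte-identical matrices.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .espf import EspfVocab, espf_encode, espf_fit

logger = logging.getLogger(__name__)

ATTRIBUTE_TYPES = ("C", "P", "E", "T")


class TableParseError(ValueError):
    pass


@dataclass
class DrugHG:
    """Typed drug heterogeneous graph.

    Attributes
    ----------
    drug_ids : list of str
        Ordered drug identifiers; fixes row order of every matrix.
    attr_ids : dict
        Per attribute type (``"C"``, ``"P"``, ``"E"``, ``"T"``) the ordered
        attribute identifier list.  Absent types are simply missing keys.
    incidence : dict
        Per attribute type a binary ``|D| x |attr|`` incidence matrix.
    ppi : ndarray or None
        Binary symmetric ``|P| x |P|`` protein–protein matrix, zero diagonal,
        indexed like ``attr_ids["P"]``.
    X : ndarray
        ``|D| x F`` binary drug feature matrix (substructure presence).
    smiles : dict
        drug_id -> SMILES string (may be empty).
    vocab : EspfVocab or None
        Fitted substructure vocabulary, if features were computed in-package.
    """

    drug_ids: list
    attr_ids: dict
    incidence: dict
    ppi: np.ndarray | None = None
    X: np.ndarray | None = None
    smiles: dict = field(default_factory=dict)
    vocab: EspfVocab | None = None
    unparseable: list = field(default_factory=list)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def available_types(self) -> tuple:
        return tuple(t for t in ATTRIBUTE_TYPES if t in self.incidence)

    def validate(self) -> None:
        for t, M in self.incidence.items():
            if not np.isin(M, (0, 1)).all():
                raise ValueError(f"incidence matrix {t} is not 0/1-valued")
            if M.shape != (self.n_drugs, len(self.attr_ids[t])):
                raise ValueError(f"incidence matrix {t} has wrong shape {M.shape}")
        if self.ppi is not None:
            if not np.array_equal(self.ppi, self.ppi.T):
                raise ValueError("PPI matrix is not symmetric")
            if np.trace(self.ppi) != 0:
                raise ValueError("PPI matrix has nonzero diagonal")


def _read_two_cols(path: str) -> list[tuple[str, str]]:
    """Parse a two-column TSV, reporting the offending line on malformed input."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise TableParseError(f"{path}:{lineno}: expected two tab-separated fields, got {line!r}")
            rows.append((parts[0], parts[1]))
    return rows


def load_attribute_table(path: str, drug_ids: list) -> tuple[np.ndarray, list]:
    """Load a drug→attribute TSV into a binary incidence matrix.

    Rows follow ``drug_ids`` order; columns follow first appearance in the
    file.  Duplicate (drug, attribute) rows collapse to a single 1.  A drug id
    absent from ``drug_ids`` is an error.
    """
    rows = _read_two_cols(path)
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    attr_index: dict[str, int] = {}
    pairs = []
    for d, a in rows:
        if d not in drug_index:
            raise KeyError(f"{path}: unknown drug id {d!r}")
        if a not in attr_index:
            attr_index[a] = len(attr_index)
        pairs.append((drug_index[d], attr_index[a]))
    M = np.zeros((len(drug_ids), len(attr_index)), dtype=np.int64)
    for i, j in pairs:
        M[i, j] = 1
    if M.shape[1] == 0:
        logger.warning("%s: empty attribute table (0 columns)", path)
    return M, list(attr_index)


def load_ppi(path: str, protein_ids: list) -> np.ndarray:
    """Load a protein-pair TSV into a symmetric zero-diagonal binary matrix.

    Pairs involving a protein not in ``protein_ids`` and self-pairs are
    dropped, with a logged count.
    """
    rows = _read_two_cols(path)
    idx = {p: i for i, p in enumerate(protein_ids)}
    M = np.zeros((len(protein_ids), len(protein_ids)), dtype=np.int64)
    dropped_unknown = dropped_self = 0
    for p, q in rows:
        if p == q:
            dropped_self += 1
            continue
        if p not in idx or q not in idx:
            dropped_unknown += 1
            continue
        M[idx[p], idx[q]] = 1
        M[idx[q], idx[p]] = 1
    if dropped_unknown:
        logger.info("%s: dropped %d PPI pairs with unknown proteins", path, dropped_unknown)
    if dropped_self:
        logger.info("%s: dropped %d self-interaction pairs", path, dropped_self)
    return M


def load_drugs(path: str) -> tuple[list, dict]:
    """Load drug_id<TAB>smiles; SMILES may be empty."""
    drug_ids, smiles = [], {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (1, 2) or not parts[0]:
                raise TableParseError(f"{path}:{lineno}: expected drug_id[<TAB>smiles]")
            drug_ids.append(parts[0])
            smiles[parts[0]] = parts[1] if len(parts) == 2 else ""
    return drug_ids, smiles


def build_drug_hg(
    drug_ids: list,
    smiles: dict,
    attribute_tables: dict,
    ppi_path: str | None = None,
    espf_min_freq: int = 2,
    espf_max_size: int = 2048,
    features: np.ndarray | None = None,
    vocab: EspfVocab | None = None,
) -> DrugHG:
    """Assemble a :class:`DrugHG` from loaded/parsed inputs.

    Parameters
    ----------
    attribute_tables : dict
        type letter -> path of a drug→attribute TSV.  Must include at least
        ``"C"`` and ``"P"``.
    ppi_path : str, optional
        Protein-pair TSV; the protein universe is restricted to drug targets,
        so PPI pairs among never-targeted proteins are dropped.
    features : ndarray, optional
        Precomputed ``|D| x F`` feature table; bypasses the in-package
        featurizer.
    """
    if "C" not in attribute_tables or "P" not in attribute_tables:
        raise ValueError("drug–substructure (C) and drug–target (P) tables are required")
    incidence, attr_ids = {}, {}
    for t in ATTRIBUTE_TYPES:
        if t in attribute_tables and attribute_tables[t] is not None:
            M, ids = load_attribute_table(attribute_tables[t], drug_ids)
            incidence[t] = M
            attr_ids[t] = ids
    ppi = None
    if ppi_path is not None:
        ppi = load_ppi(ppi_path, attr_ids["P"])

    unparseable: list = []
    if features is not None:
        X = np.asarray(features)
        if X.shape[0] != len(drug_ids):
            raise ValueError("precomputed feature table row count != number of drugs")
    else:
        smiles_list = [smiles.get(d, "") for d in drug_ids]
        if vocab is None:
            corpus = [s for s in smiles_list if s]
            if corpus:
                vocab = espf_fit(corpus, min_freq=espf_min_freq, max_size=espf_max_size)
            else:
                vocab = EspfVocab(tokens=[], min_freq=espf_min_freq, max_size=espf_max_size)
        X = np.zeros((len(drug_ids), len(vocab.tokens)), dtype=np.int64)
        for i, s in enumerate(smiles_list):
            vec, ok = espf_encode(s, vocab)
            X[i] = vec
            if not ok and s:
                unparseable.append(drug_ids[i])

    isolated = [
        d for i, d in enumerate(drug_ids)
        if all(M[i].sum() == 0 for M in incidence.values())
    ]
    if isolated:
        logger.warning("%d drugs have no attributes in any table: %s",
                       len(isolated), ", ".join(isolated[:5]))

    hg = DrugHG(drug_ids=drug_ids, attr_ids=attr_ids, incidence=incidence,
                ppi=ppi, X=X, smiles=dict(smiles), vocab=vocab,
                unparseable=unparseable)
    hg.validate()
    return hg


def build_drug_hg_from_files(
    drugs_path: str,
    attribute_tables: dict,
    ppi_path: str | None = None,
    **kwargs,
) -> DrugHG:
    drug_ids, smiles = load_drugs(drugs_path)
    return build_drug_hg(drug_ids, smiles, attribute_tables, ppi_path, **kwargs)


def write_tables(hg: DrugHG, out_dir: str) -> None:
    """Write the graph back to the TSV formats it was built from."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "drugs.tsv"), "w", encoding="utf-8") as fh:
        for d in hg.drug_ids:
            fh.write(f"{d}\t{hg.smiles.get(d, '')}\n")
    for t, M in hg.incidence.items():
        ids = hg.attr_ids[t]
        # attribute-major row order: first appearance on reload == column order
        with open(os.path.join(out_dir, f"drug_attr_{t}.tsv"), "w", encoding="utf-8") as fh:
            for j, a in enumerate(ids):
                for i in np.flatnonzero(M[:, j]):
                    fh.write(f"{hg.drug_ids[i]}\t{a}\n")
    if hg.ppi is not None:
        prot = hg.attr_ids["P"]
        with open(os.path.join(out_dir, "ppi.tsv"), "w", encoding="utf-8") as fh:
            iu, ju = np.triu_indices_from(hg.ppi, k=1)
            for i, j in zip(iu, ju):
                if hg.ppi[i, j]:
                    fh.write(f"{prot[i]}\t{prot[j]}\n")
    if hg.X is not None:
        np.savetxt(os.path.join(out_dir, "features.tsv"), hg.X, fmt="%d", delimiter="\t")


def write_ddis(pairs: list, path: str) -> None:
    pd.DataFrame(pairs, columns=["drug_a", "drug_b", "event_id"]).to_csv(
        path, sep="\t", header=False, index=False)


def load_ddis(path: str) -> list:
    """Load drug_a<TAB>drug_b<TAB>event_id triples."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TableParseError(f"{path}:{lineno}: expected three tab-separated fields")
            out.append((parts[0], parts[1], int(parts[2])))
    return out
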