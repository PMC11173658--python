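"""Frequency-based SMILES substructure featurization.

Drug feature vectors are binary indicators over a vocabulary of frequent
SMILES substrings, learned with a byte-pair-encoding-style merge procedure:
starting from single atom/bond tokens, the most frequent adjacent token pair
is merged repeatedly while its corpus count stays above a threshold
(explainable substructure partition fingerprints).  Encoding a SMILES then
greedily segments it into the longest matching vocabulary tokens.

SMILES strings that RDKit cannot parse are flagged; their vectors fall back
to character-unigram indicators so every drug keeps a nonempty feature row
when any of its characters are in the vocabulary.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

# Two-letter organic-subset atoms and bracket atoms kept as single tokens.
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Cl|Br|.)")


@dataclass(frozen=True)
class EspfVocab:
    """Ordered substructure vocabulary; feature dimension is ``len(tokens)``."""

    tokens: list
    min_freq: int
    max_size: int

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")

    @property
    def size(self) -> int:
        return len(self.tokens)


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES into atom/bond tokens (Cl, Br, [..] kept whole)."""
    return _TOKEN_RE.findall(smiles)


def smiles_parseable(smiles: str) -> bool:
    if not smiles:
        return False
    return Chem.MolFromSmiles(smiles, sanitize=False) is not None


def espf_fit(smiles_list: list[str], min_freq: int = 2, max_size: int = 2048) -> EspfVocab:
    """Learn a substructure vocabulary from a SMILES corpus.

    Iteratively merges the most frequent adjacent token pair whose corpus
    count is at least ``min_freq`` until the vocabulary reaches ``max_size``
    tokens or no pair qualifies.  Ties are broken lexicographically, so the
    result is a pure function of the corpus.
    """
    if not smiles_list:
        raise ValueError("ESPF fitting requires a non-empty SMILES corpus")
    sequences = [tokenize_smiles(s) for s in smiles_list if s]
    unigrams: dict[str, None] = {}
    for seq in sequences:
        for tok in seq:
            unigrams.setdefault(tok, None)
    vocab = list(unigrams)
    while len(vocab) < max_size:
        pair_counts: Counter = Counter()
        for seq in sequences:
            for a, b in zip(seq, seq[1:]):
                pair_counts[(a, b)] += 1
        eligible = [(cnt, pair) for pair, cnt in pair_counts.items() if cnt >= min_freq]
        if not eligible:
            break
        # most frequent first; ties by lexicographically smallest pair
        best = min(eligible, key=lambda cp: (-cp[0], cp[1]))[1]
        merged = best[0] + best[1]
        new_sequences = []
        for seq in sequences:
            out, i = [], 0
            while i < len(seq):
                if i + 1 < len(seq) and (seq[i], seq[i + 1]) == best:
                    out.append(merged)
                    i += 2
                else:
                    out.append(seq[i])
                    i += 1
            new_sequences.append(out)
        sequences = new_sequences
        if merged not in vocab:
            vocab.append(merged)
    return EspfVocab(tokens=vocab, min_freq=min_freq, max_size=max_size)


def _greedy_segments(smiles: str, token_set: set) -> list[str]:
    toks = tokenize_smiles(smiles)
    # work on the raw string but align to atom-token boundaries
    joined = toks
    found, i = [], 0
    while i < len(joined):
        match = None
        for j in range(len(joined), i, -1):
            cand = "".join(joined[i:j])
            if cand in token_set:
                match = (cand, j)
                break
        if match is None:
            i += 1  # unknown token skipped
        else:
            found.append(match[0])
            i = match[1]
    return found


def espf_encode(smiles: str, vocab: EspfVocab) -> tuple[np.ndarray, bool]:
    """Encode a SMILES as a binary presence vector over ``vocab``.

    Returns ``(vector, parseable)``.  Unparseable SMILES fall back to
    character-unigram presence; empty SMILES yield a zero vector.
    """
    vec = np.zeros(vocab.size, dtype=np.int64)
    if not smiles:
        return vec, False
    index = {t: i for i, t in enumerate(vocab.tokens)}
    parseable = smiles_parseable(smiles)
    if parseable:
        segments = _greedy_segments(smiles, set(index))
    else:
        segments = [t for t in tokenize_smiles(smiles) if t in index]
    for t in segments:
        vec[index[t]] = 1
    return vec, parseable
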