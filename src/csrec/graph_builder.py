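"""Medication co-occurrence, DDI and per-visit bipartite graph construction.

The medication graph combines a visit-level co-prescription count matrix
A_mm with a binary contraindication matrix A_ddi as  G = A_mm − λ·A_ddi,
negatives clipped to zero (a negative edge weight has no meaning for the
attention layer that consumes the graph).  The three heterogeneous graphs
(diagnosis–procedure, medication–diagnosis, medication–procedure) are
complete bipartite over each visit's active codes, with the medication side
taken from the previous visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .cohort_io import MultiHotTriple, Vocabulary

logger = logging.getLogger(__name__)


@dataclass
class SymmetricAdjacency:
    """Symmetric non-negative adjacency with a zero diagonal."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("adjacency weights must be non-negative")
        self.weights = w

    @property
    def size(self) -> int:
        return self.weights.shape[0]


@dataclass
class CombinedMedGraph:
    """λ-combined medication graph; edges are the strictly positive entries."""

    weights: np.ndarray
    lam: float

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.weights[i] > 0)


class BipartitePair(str, Enum):
    DP = "dp"  # diagnosis–procedure, within-visit
    MD = "md"  # previous-visit medications – current diagnoses
    MP = "mp"  # previous-visit medications – current procedures


@dataclass
class BipartiteEdges:
    pair: BipartitePair
    left: np.ndarray   # active indices on the left entity type
    right: np.ndarray  # active indices on the right entity type

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i in self.left for j in self.right}

    @property
    def n_edges(self) -> int:
        return len(self.left) * len(self.right)


def build_cooccurrence(med_history: Iterable[frozenset[str] | set[str]],
                       vocab: Vocabulary) -> SymmetricAdjacency:
    """Count, over visits, how often each unordered medication pair co-occurs."""
    n = vocab.n_med
    A = np.zeros((n, n), dtype=np.float64)
    for visit_meds in med_history:
        idx = []
        for code in visit_meds:
            if code not in vocab.med_index:
                raise KeyError(f"unknown medication code {code!r}")
            idx.append(vocab.med_index[code])
        idx = sorted(idx)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                A[idx[a], idx[b]] += 1
                A[idx[b], idx[a]] += 1
    return SymmetricAdjacency(weights=A)


def build_cooccurrence_from_multihot(
        med_vectors: Sequence[np.ndarray], n_med: int) -> SymmetricAdjacency:
    """Same counting, over already-encoded medication indicator vectors."""
    A = np.zeros((n_med, n_med), dtype=np.float64)
    for v in med_vectors:
        idx = np.flatnonzero(v)
        if len(idx) >= 2:
            A[np.ix_(idx, idx)] += 1
    np.fill_diagonal(A, 0)
    return SymmetricAdjacency(weights=A)


def build_ddi_matrix(pairs: Iterable[tuple[str, str]],
                     vocab: Vocabulary) -> SymmetricAdjacency:
    """Binary symmetric contraindication matrix; unknown codes are skipped."""
    n = vocab.n_med
    A = np.zeros((n, n), dtype=np.float64)
    for a, b in pairs:
        if a == b:
            logger.warning("self-pair (%s, %s) rejected", a, b)
            continue
        if a not in vocab.med_index or b not in vocab.med_index:
            logger.warning("DDI pair (%s, %s) references unknown code; skipped", a, b)
            continue
        i, j = vocab.med_index[a], vocab.med_index[b]
        A[i, j] = A[j, i] = 1.0
    return SymmetricAdjacency(weights=A)


def combine_medication_graph(a_mm: SymmetricAdjacency, a_ddi: SymmetricAdjacency,
                             lam: float = 1.0) -> CombinedMedGraph:
    """Entrywise A_mm − λ·A_ddi with negatives clipped to zero."""
    if a_mm.size != a_ddi.size:
        raise ValueError(f"size mismatch: {a_mm.size} vs {a_ddi.size}")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    w = np.clip(a_mm.weights - lam * a_ddi.weights, 0.0, None)
    return CombinedMedGraph(weights=w, lam=lam)


def build_visit_bipartite(current: MultiHotTriple, pair: BipartitePair | str,
                          prev_meds: np.ndarray | None = None) -> BipartiteEdges:
    """Complete bipartite edge set for one visit.

    For the medication-sided pairs the left side is the PREVIOUS visit's
    medication vector; pass ``prev_meds=None`` (or all-zero) at the first
    visit to get an empty edge set.
    """
    pair = BipartitePair(pair)
    if pair is BipartitePair.DP:
        left, right = current.active("d"), current.active("p")
    else:
        left = (np.flatnonzero(prev_meds) if prev_meds is not None
                else np.array([], dtype=int))
        right = current.active("d" if pair is BipartitePair.MD else "p")
    return BipartiteEdges(pair=pair, left=left, right=right)


def export_adjacency(adj: SymmetricAdjacency | CombinedMedGraph, path) -> None:
    """Dump the nonzero upper triangle as 'i j w' text, one edge per line."""
    w = adj.weights
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"% symmetric {w.shape[0]} {w.shape[0]}\n")
        ii, jj = np.nonzero(np.triu(w))
        for i, j in zip(ii, jj):
            fh.write(f"{i} {j} {w[i, j]:g}\n")
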