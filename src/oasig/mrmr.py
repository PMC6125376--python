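"""Greedy minimal-redundancy–maximal-relevance (mRMR) gene ranking.

At each step the candidate g maximizing

    relevance(g, labels) − mean over selected genes s of I(g, s)

is moved from the candidate pool to the selected list, where I is plug-in
mutual information on the discretized expression levels. The first pick has an
empty selected set, so its score is pure relevance (the empty-set redundancy
is defined as 0). Ties are broken by input gene order (first wins); scores
within 1e-9 bits are treated as tied, so that mathematically equal scores
reached through different floating-point summation orders still resolve to
the earlier gene.

Pairwise gene–gene MIs are computed once, when a gene is first selected, and
accumulated into running redundancy sums — arithmetically identical to naive
recomputation at every step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .discretize import DiscretizedMatrix, mutual_information

#: scores closer than this (in bits) count as tied for input-order tie-breaking
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class RankedGene:
    rank: int
    gene_id: str
    score: float  # relevance − mean redundancy, at selection time (bits)


@dataclass
class RankedGeneList:
    """Ordered mRMR ranking; ranks are 1..N consecutive, gene IDs unique."""

    entries: list[RankedGene]

    def __post_init__(self) -> None:
        ranks = [e.rank for e in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be consecutive from 1")
        ids = [e.gene_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ID in ranking")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.entries):
            raise ValueError(f"k must be in 1..{len(self.entries)}")
        return self.gene_ids[:k]

    def rank_of(self, gene_id: str) -> int:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e.rank
        raise KeyError(gene_id)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Rank\tName\tmRMR score (bits)\n")
            for e in self.entries:
                fh.write(f"{e.rank}\t{e.gene_id}\t{e.score:.6f}\n")


def relevance(g, labels) -> float:
    """Mutual information (bits) between a discretized gene and the labels."""
    return mutual_information(g, labels)


def redundancy(g, selected: Sequence) -> float:
    """Mean MI (bits) between gene g and the selected genes; 0 if none selected."""
    if len(selected) == 0:
        return 0.0
    return sum(mutual_information(g, s) for s in selected) / len(selected)


def mrmr_rank(
    dm: DiscretizedMatrix, labels, top_n: int | None = 300
) -> RankedGeneList:
    """Rank genes by the greedy mRMR criterion.

    Parameters
    ----------
    dm:
        Discretized expression matrix.
    labels:
        Per-sample categorical labels (any encoding).
    top_n:
        Number of genes to rank; ``None`` ranks all. Must satisfy
        1 ≤ top_n ≤ number of genes.
    """
    n_genes = dm.n_genes
    if top_n is None:
        top_n = n_genes
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > n_genes:
        raise ValueError(f"top_n={top_n} exceeds the {n_genes} available genes")
    labels = np.asarray(labels)
    if labels.shape[0] != dm.n_samples:
        raise ValueError("label length does not match sample count")

    X = dm.codes
    rel = np.array([mutual_information(X[:, j], labels) for j in range(n_genes)])
    red_sum = np.zeros(n_genes)
    selected = np.zeros(n_genes, dtype=bool)
    entries: list[RankedGene] = []
    for m in range(top_n):
        scores = rel if m == 0 else rel - red_sum / m
        scores = np.where(selected, -np.inf, scores)
        # tie-break by input order: first candidate within tolerance of the max
        j = int(np.argmax(scores >= scores.max() - _TIE_TOL))
        entries.append(RankedGene(m + 1, dm.gene_ids[j], float(scores[j])))
        selected[j] = True
        if m + 1 < top_n:
            gj = X[:, j]
            for g in np.nonzero(~selected)[0]:
                red_sum[g] += mutual_information(gj, X[:, g])
    return RankedGeneList(entries)
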