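"""Post-hoc signature statistics: gene-set overlap enrichment and class direction.

``overlap_test`` asks whether two gene sets drawn from a common universe share
more members than chance: the p-value is the upper tail P(X ≥ k) of the
hypergeometric distribution (the enrichment convention), and the effect size
is the sample odds ratio of the implied 2x2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .io import CASE, CONTROL, ExpressionMatrix


@dataclass(frozen=True)
class OverlapResult:
    """2x2 membership table for two gene sets in a universe of size N.

    odds_ratio = (overlap · neither) / (a_only · b_only); a zero denominator
    with non-zero overlap gives ``inf``, zero overlap gives 0.
    """

    overlap: int
    a_only: int
    b_only: int
    neither: int
    universe: int
    p_value: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.overlap + self.a_only + self.b_only + self.neither != self.universe:
            raise ValueError("table counts must sum to the universe size")


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> OverlapResult:
    """Upper-tail hypergeometric overlap test between two gene-ID sets.

    IDs are compared case-insensitively. ``universe_size`` is the number of
    genes the two sets were drawn from (e.g. all genes on the platform) and
    must be at least the size of their union.
    """
    a = {str(g).casefold() for g in set_a}
    b = {str(g).casefold() for g in set_b}
    n_union = len(a | b)
    if universe_size < n_union:
        raise ValueError(
            f"universe ({universe_size}) smaller than the union of the sets ({n_union})"
        )
    k = len(a & b)
    a_only = len(a) - k
    b_only = len(b) - k
    neither = universe_size - k - a_only - b_only
    # P(X >= k) for X ~ Hypergeom(N, |a|, |b|)
    p = float(hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    if k == 0:
        odds = 0.0
    elif a_only == 0 or b_only == 0:
        odds = math.inf
    else:
        odds = (k * neither) / (a_only * b_only)
    return OverlapResult(k, a_only, b_only, neither, universe_size, p, odds)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments skipped."""
    genes: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return genes


def write_overlap(res: OverlapResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("overlap\ta_only\tb_only\tneither\tuniverse\tp_value\todds_ratio\n")
        fh.write(
            f"{res.overlap}\t{res.a_only}\t{res.b_only}\t{res.neither}\t"
            f"{res.universe}\t{res.p_value:.6g}\t{res.odds_ratio:.6g}\n"
        )


@dataclass(frozen=True)
class GeneDirection:
    gene_id: str
    case_mean: float
    control_mean: float
    direction: str  # "up-in-case" | "up-in-control" | "tied"


@dataclass
class DirectionSummary:
    """Per-gene class means and the sign of the case − control difference."""

    rows: list[GeneDirection]

    def direction_of(self, gene_id: str) -> str:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r.direction
        raise KeyError(gene_id)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_id\tcase_mean\tcontrol_mean\tdirection\n")
            for r in self.rows:
                fh.write(
                    f"{r.gene_id}\t{r.case_mean:.6g}\t{r.control_mean:.6g}\t{r.direction}\n"
                )


def class_direction(em: ExpressionMatrix, genes: Sequence[str]) -> DirectionSummary:
    """Per-gene case/control means for the given genes, in the given order.

    A gene whose case mean exceeds its control mean is ``up-in-case``
    (highly expressed in disease samples); an exact tie is ``tied``.
    """
    case_counts = em.labels == CASE
    if not case_counts.any() or not (em.labels == CONTROL).any():
        raise ValueError("both classes must be present")
    rows: list[GeneDirection] = []
    for g in genes:
        if g not in em.values.columns:
            raise KeyError(f"unknown gene ID {g!r}")
        col = em.values[g]
        cm = float(col[case_counts].mean())
        km = float(col[~case_counts].mean())
        if cm > km:
            d = "up-in-case"
        elif cm < km:
            d = "up-in-control"
        else:
            d = "tied"
        rows.append(GeneDirection(g, cm, km, d))
    return DirectionSummary(rows)
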