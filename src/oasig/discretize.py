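"""Mean±SD discretization and plug-in mutual information.

Mutual information is only defined here between categorical variables, so each
gene's continuous expression is first mapped to three ordered levels using the
gene's own mean and standard deviation as thresholds:

* ``low``  — value < mean − SD
* ``mid``  — mean − SD ≤ value ≤ mean + SD (boundaries inclusive)
* ``high`` — value > mean + SD

The SD is the sample standard deviation (n−1 denominator) by default. A
constant gene has SD 0 and discretizes to all-``mid``, carrying no information.

The statistics are computed per gene over *all* samples before any
cross-validation — see the methods note for the selection-bias caveat this
implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import CASE, ExpressionMatrix

LOW, MID, HIGH = 0, 1, 2
LEVELS = ("low", "mid", "high")


@dataclass
class DiscretizedMatrix:
    """Per-gene three-level codes, samples x genes, gene order preserved."""

    codes: np.ndarray  # int8, shape (n_samples, n_genes), values in {0,1,2}
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("codes shape does not match sample/gene IDs")

    @property
    def n_genes(self) -> int:
        return self.codes.shape[1]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    def gene(self, gene_id: str) -> np.ndarray:
        return self.codes[:, self.gene_ids.index(gene_id)]


def discretize(values, ddof: int = 1) -> np.ndarray:
    """Map a real vector to {low, mid, high} codes at mean±SD thresholds.

    Returns an int8 array with 0=low, 1=mid, 2=high. Boundary values are
    assigned to ``mid``. Requires at least two values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if v.size < 2:
        raise ValueError("need at least 2 values to estimate mean and SD")
    mu = v.mean()
    sd = v.std(ddof=ddof)
    codes = np.full(v.shape, MID, dtype=np.int8)
    codes[v < mu - sd] = LOW
    codes[v > mu + sd] = HIGH
    return codes


def discretize_matrix(em: ExpressionMatrix, ddof: int = 1) -> DiscretizedMatrix:
    """Discretize every gene of an expression matrix at its own mean±SD."""
    X = em.values.to_numpy()
    codes = np.empty(X.shape, dtype=np.int8)
    for j in range(X.shape[1]):
        codes[:, j] = discretize(X[:, j], ddof=ddof)
    return DiscretizedMatrix(codes, em.gene_ids, em.sample_ids)


def encode_labels(labels) -> np.ndarray:
    """Encode case/control labels as int8 codes (control=0, case=1)."""
    arr = np.asarray(labels)
    return (arr == CASE).astype(np.int8)


def contingency(x, y) -> np.ndarray:
    """Joint count table of two equal-length categorical vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    xi, nx = _as_codes(x)
    yi, ny = _as_codes(y)
    return np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)


def _as_codes(v: np.ndarray) -> tuple[np.ndarray, int]:
    if np.issubdtype(v.dtype, np.integer):
        vmax = int(v.max()) if v.size else 0
        if v.min() >= 0 and vmax < 16:
            return v.astype(np.intp), vmax + 1
    inv = np.unique(v, return_inverse=True)[1]
    return inv.astype(np.intp), int(inv.max()) + 1


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two categorical vectors, in bits.

    I = Σ p̂(a,b) · log2( p̂(a,b) / (p̂(a)·p̂(b)) ) over the joint empirical
    distribution; empty cells contribute 0. Exactly symmetric in its
    arguments (terms are accumulated with exact summation) and never
    negative.
    """
    c = contingency(x, y).astype(float)
    n = c.sum()
    pxy = c / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    terms = []
    nz = np.nonzero(pxy)
    for a, b in zip(*nz):
        p = pxy[a, b]
        terms.append(p * math.log2(p / (px[a] * py[b])))
    return max(math.fsum(terms), 0.0)


def entropy(x) -> float:
    """Plug-in Shannon entropy of a categorical vector, in bits."""
    return mutual_information(x, x)


def write_discretized(dm: DiscretizedMatrix, path) -> None:
    """Dump codes as TSV with levels written as -1/0/1 (low/mid/high)."""
    import pandas as pd

    df = pd.DataFrame(
        dm.codes.astype(int) - 1, index=dm.sample_ids, columns=dm.gene_ids
    )
    df.rename_axis("sample_id").to_csv(path, sep="\t")
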