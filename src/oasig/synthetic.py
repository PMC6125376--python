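"""Synthetic labeled expression cohorts with known ground truth.

The generator emulates the statistical structure the signature-discovery
pipeline assumes: an unbalanced two-class cohort (default 106 cases vs 33
controls, the shape of the motivating blood study), a small set of
class-informative genes whose means are shifted between classes by
``effect_size`` standard deviations, blocks of redundant genes that are noisy
copies of informative ones, and a large background of null genes drawn
identically for both classes.

Values are Gaussian on a microarray-like log-intensity scale. One shared
pseudo-random stream is consumed gene-by-gene (informative genes first, then
redundant copies, then nulls, samples in cohort order within each gene), so
enlarging the null background does not reshuffle the informative genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, ExpressionMatrix, write_expression_table, write_labels


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``effect_size`` is the standardized mean shift δ between classes, in units
    of ``base_sd`` (case mean = base_mean + δ·base_sd). ``redundancy_noise_sd``
    is the SD of independent Gaussian noise added to each redundant copy of an
    informative gene.
    """

    n_case: int = 106
    n_control: int = 33
    n_informative: int = 5
    n_redundant_per_informative: int = 1
    n_null: int = 200
    effect_size: float = 3.0
    redundancy_noise_sd: float = 0.1
    base_mean: float = 8.0
    base_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per class")
        for name in ("n_informative", "n_redundant_per_informative", "n_null"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be > 0")
        if self.redundancy_noise_sd < 0:
            raise ValueError("redundancy_noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_control

    @property
    def n_genes(self) -> int:
        return self.n_informative * (1 + self.n_redundant_per_informative) + self.n_null


@dataclass
class SyntheticTruth:
    """Ground-truth gene roles; the three groups partition all gene IDs."""

    informative: set[str]
    redundant_map: dict[str, str]  # redundant gene -> parent informative gene
    null: set[str]

    def role(self, gene_id: str) -> str:
        if gene_id in self.informative:
            return "informative"
        if gene_id in self.redundant_map:
            return "redundant"
        if gene_id in self.null:
            return "null"
        raise KeyError(gene_id)

    def canonical(self, gene_id: str) -> str:
        """Map a redundant copy to its parent; other genes map to themselves."""
        return self.redundant_map.get(gene_id, gene_id)

    @property
    def all_gene_ids(self) -> set[str]:
        return self.informative | set(self.redundant_map) | self.null


def generate_cohort(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a labeled cohort from ``spec``; same spec+seed is bit-identical.

    Sample order is cases first, then controls. Informative genes get
    class-specific means; each redundant gene is its parent's values plus
    independent noise; null genes ignore the class entirely.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    labels = np.array([CASE] * spec.n_case + [CONTROL] * spec.n_control)
    sample_ids = [f"OA{i+1:03d}" for i in range(spec.n_case)] + [
        f"CT{i+1:03d}" for i in range(spec.n_control)
    ]
    shift = np.where(labels == CASE, spec.effect_size * spec.base_sd, 0.0)

    cols: dict[str, np.ndarray] = {}
    informative_ids: list[str] = []
    for i in range(spec.n_informative):
        gid = f"INF{i+1:03d}"
        cols[gid] = spec.base_mean + shift + rng.normal(0.0, spec.base_sd, n)
        informative_ids.append(gid)
    redundant_map: dict[str, str] = {}
    for i, parent in enumerate(informative_ids):
        for j in range(spec.n_redundant_per_informative):
            gid = f"RED{i+1:03d}.{j+1}"
            cols[gid] = cols[parent] + rng.normal(0.0, spec.redundancy_noise_sd, n)
            redundant_map[gid] = parent
    null_ids = [f"NUL{i+1:04d}" for i in range(spec.n_null)]
    for gid in null_ids:
        cols[gid] = spec.base_mean + rng.normal(0.0, spec.base_sd, n)

    values = pd.DataFrame(cols, index=sample_ids)
    em = ExpressionMatrix(values, pd.Series(labels, index=sample_ids, name="label"))
    truth = SyntheticTruth(set(informative_ids), redundant_map, set(null_ids))
    return em, truth


def write_cohort(
    em: ExpressionMatrix, truth: SyntheticTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write matrix.tsv (genes in rows), labels.tsv and truth.tsv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "labels": out / "labels.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression_table(em.values, paths["matrix"], orientation="probes_in_rows")
    write_labels(em.labels, paths["labels"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\trole\n")
        for gid in em.gene_ids:
            fh.write(f"{gid}\t{truth.role(gid)}\n")
    return paths
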