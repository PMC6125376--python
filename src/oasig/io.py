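"""Expression-matrix I/O: TSV parsing, probe-to-gene collapsing, quantile normalization.

Matrices are held as :class:`pandas.DataFrame` in **samples x features**
orientation throughout the package, whatever the on-disk layout. Labels are a
two-level category (``"case"`` / ``"control"``), with the case class meaning the
disease phenotype (osteoarthritis in the motivating cohort).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: label spellings accepted by :func:`read_labels` (matched case-insensitively)
DEFAULT_CASE_ALIASES = ("case", "oa", "disease", "patient", "1")
DEFAULT_CONTROL_ALIASES = ("control", "ctrl", "healthy", "normal", "0")


class ParseError(ValueError):
    """Raised for malformed expression tables; the message names the line."""


@dataclass
class ProbeMatrix:
    """Probe-level expression, samples x probes, all values finite."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate sample ID {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate probe ID {dup!r}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ParseError("non-finite value in expression matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionMatrix:
    """Gene-level expression (samples x genes) with per-sample binary labels.

    ``labels`` is a Series indexed by sample ID with values ``"case"`` /
    ``"control"``, covering every sample in ``values``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate gene IDs")
        missing = [s for s in self.values.index if s not in self.labels.index]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        self.labels = self.labels.reindex(self.values.index)
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"labels must be {CASE!r}/{CONTROL!r}, got {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_case, n_control)."""
        vc = self.labels.value_counts()
        return int(vc.get(CASE, 0)), int(vc.get(CONTROL, 0))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _tokenize(path: Path) -> list[tuple[int, list[str]]]:
    """Split a TSV into (1-based line number, fields); GEO-style '!'-comment
    lines and blank lines are skipped, surrounding double quotes stripped."""
    out: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            out.append((lineno, fields))
    return out


def read_expression_table(path: str | Path, orientation: str = "probes_in_rows") -> ProbeMatrix:
    """Read a TSV expression table into a samples x probes :class:`ProbeMatrix`.

    Parameters
    ----------
    path:
        TSV file with one header row of IDs and an ID column. Lines starting
        with ``!`` (GEO series-matrix metadata) or ``#`` are skipped.
    orientation:
        ``"probes_in_rows"`` (the common GEO layout: one row per probe, one
        column per sample) or ``"samples_in_rows"``.

    Raises
    ------
    ParseError
        On ragged rows, non-numeric cells, or duplicated IDs; the message
        names the offending line.
    """
    if orientation not in ("probes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    lines = _tokenize(path)
    if not lines:
        raise ParseError(f"{path}: no data lines")
    header_no, header = lines[0]
    col_ids = header[1:]
    ncol = len(header)
    if len(set(col_ids)) != len(col_ids):
        dup = next(c for i, c in enumerate(col_ids) if c in col_ids[:i])
        raise ParseError(f"{path} line {header_no}: duplicate column ID {dup!r}")
    row_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, fields in lines[1:]:
        if len(fields) != ncol:
            raise ParseError(
                f"{path} line {lineno}: expected {ncol} fields, got {len(fields)}"
            )
        rid = fields[0]
        if rid in seen:
            raise ParseError(f"{path} line {lineno}: duplicate row ID {rid!r}")
        seen.add(rid)
        try:
            vals = [float(v) for v in fields[1:]]
        except ValueError:
            bad = next(v for v in fields[1:] if not _is_number(v))
            raise ParseError(
                f"{path} line {lineno}: non-numeric value {bad!r}"
            ) from None
        row_ids.append(rid)
        rows.append(vals)
    df = pd.DataFrame(rows, index=row_ids, columns=col_ids, dtype=float)
    if orientation == "probes_in_rows":
        df = df.T
    return ProbeMatrix(df)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_labels(
    path: str | Path,
    case_aliases: Iterable[str] = DEFAULT_CASE_ALIASES,
    control_aliases: Iterable[str] = DEFAULT_CONTROL_ALIASES,
) -> pd.Series:
    """Read a two-column TSV (sample_id, label) into a case/control Series.

    Label spellings are matched case-insensitively against the alias lists
    (e.g. ``OA`` maps to ``"case"``). An optional single header line is
    tolerated.
    """
    case_set = {a.casefold() for a in case_aliases}
    control_set = {a.casefold() for a in control_aliases}
    ids: list[str] = []
    labs: list[str] = []
    for i, (lineno, fields) in enumerate(_tokenize(Path(path))):
        if len(fields) != 2:
            raise ParseError(f"{path} line {lineno}: expected 2 fields, got {len(fields)}")
        sid, lab = fields
        key = lab.casefold()
        if key in case_set:
            labs.append(CASE)
        elif key in control_set:
            labs.append(CONTROL)
        elif i == 0:
            continue  # header line
        else:
            raise ParseError(f"{path} line {lineno}: unrecognized label {lab!r}")
        ids.append(sid)
    s = pd.Series(labs, index=ids, name="label")
    if s.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ID in label file")
    return s


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (probe_id, gene_id) into a probe-to-gene dict."""
    mapping: dict[str, str] = {}
    for i, (lineno, fields) in enumerate(_tokenize(Path(path))):
        if len(fields) != 2:
            raise ParseError(f"{path} line {lineno}: expected 2 fields, got {len(fields)}")
        probe, gene = fields
        if i == 0 and probe.casefold() in ("probe", "probe_id", "id"):
            continue
        mapping[probe] = gene
    return mapping


def write_expression_table(
    values: pd.DataFrame, path: str | Path, orientation: str = "probes_in_rows"
) -> None:
    """Write a samples x features frame as TSV (default: features in rows)."""
    df = values.T if orientation == "probes_in_rows" else values
    df = df.rename_axis("ID")
    df.to_csv(path, sep="\t")  # default float repr round-trips exactly


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename_axis("sample_id").rename("label").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes(
    pm: ProbeMatrix,
    mapping: Mapping[str, str] | pd.Series,
    labels: pd.Series,
) -> ExpressionMatrix:
    """Collapse probes to genes by averaging probes that map to the same gene.

    Each gene's expression in a sample is the arithmetic mean over that gene's
    probes. Gene order follows the first appearance of each gene in probe
    order. Probes absent from ``mapping`` are dropped (a count is logged).
    """
    if isinstance(mapping, pd.Series):
        mapping = mapping.to_dict()
    if not mapping:
        raise ValueError("empty probe-to-gene mapping")
    probe_ids = pm.probe_ids
    mapped = [p for p in probe_ids if p in mapping]
    n_unmapped = len(probe_ids) - len(mapped)
    if n_unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_unmapped)
    if not mapped:
        raise ValueError("no probe in the matrix is covered by the mapping")
    gene_order: list[str] = []
    seen: set[str] = set()
    for p in mapped:
        g = mapping[p]
        if g not in seen:
            seen.add(g)
            gene_order.append(g)
    sub = pm.values[mapped]
    genes = sub.T.groupby([mapping[p] for p in mapped], sort=False).mean().T
    genes = genes[gene_order]
    return ExpressionMatrix(genes, labels)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize_values(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize a samples x genes array across samples.

    The reference distribution is the across-sample mean of per-sample sorted
    values; each sample's value at rank *r* is replaced by the reference value
    at rank *r*. Tied values within a sample receive the mean of the reference
    values at their tied ranks, so ranks never have to be broken arbitrarily.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one sample and one gene")
    ref = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    n = X.shape[1]
    for i in range(X.shape[0]):
        row = X[i]
        order = np.argsort(row, kind="stable")
        sorted_vals = row[order]
        j = 0
        while j < n:
            k = j
            while k + 1 < n and sorted_vals[k + 1] == sorted_vals[j]:
                k += 1
            out[i, order[j : k + 1]] = ref[j : k + 1].mean()
            j = k + 1
    return out


def quantile_normalize(em: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize the gene matrix across samples (labels unchanged)."""
    vals = quantile_normalize_values(em.values.to_numpy())
    return ExpressionMatrix(
        pd.DataFrame(vals, index=em.values.index, columns=em.values.columns),
        em.labels,
    )
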