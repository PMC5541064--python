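"""Readers and writers for the text formats the pipeline touches.

Expression matrices travel as GCT 1.3 (genes as rows, perturbation trials
as columns, one column-metadata row ``pert_iname`` carrying the perturbing
drug of each trial) or as the equivalent two-line-header TSV. Label tables,
feature-set tables and output matrices are plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ATC_LETTERS",
    "ExpressionTable",
    "GctFormatError",
    "read_gct",
    "write_gct",
    "read_label_table",
    "write_label_table",
    "read_feature_sets",
    "write_feature_sets",
    "write_matrix",
    "read_matrix",
]

#: First-level Anatomical Therapeutic Chemical classes (14 therapeutic properties).
ATC_LETTERS: tuple[str, ...] = tuple("ABCDGHJLMNPRSV")


class GctFormatError(ValueError):
    """Malformed GCT/TSV expression file."""


@dataclass
class ExpressionTable:
    """Trials-by-genes Z-score matrix with per-trial drug identity.

    ``values`` is samples x genes; ``drug_of_sample`` maps every sample id
    to the drug whose perturbation produced that trial.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    drug_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise GctFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GctFormatError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.drug_of_sample]
        if missing:
            raise GctFormatError(f"samples without a drug assignment: {missing[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def drugs(self) -> list[str]:
        """Unique drugs in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.drug_of_sample[s], None)
        return list(seen)

    def samples_of(self, drug: str) -> list[int]:
        """Row indices of all trials of one drug."""
        return [i for i, s in enumerate(self.sample_ids) if self.drug_of_sample[s] == drug]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def _parse_body(lines: list[str], path: str) -> ExpressionTable:
    """Parse the shared two-line-header body (sample row, pert_iname row, gene rows)."""
    if len(lines) < 3:
        raise GctFormatError(f"{path}: too few lines for an expression table")
    header = lines[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    meta = lines[1].rstrip("\n").split("\t")
    if meta[0] != "pert_iname":
        raise GctFormatError(f"{path}: expected a 'pert_iname' metadata row, got {meta[0]!r}")
    if len(meta) != len(header):
        raise GctFormatError(f"{path}: pert_iname row width does not match sample header")
    drug_of_sample = dict(zip(sample_ids, meta[1:]))
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[2:]:
        ln = ln.rstrip("\n")
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise GctFormatError(
                f"{path}: gene row {parts[0]!r} has {len(parts) - 1} values, "
                f"expected {len(sample_ids)}"
            )
        gene_ids.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise GctFormatError(f"{path}: non-numeric value in row {parts[0]!r}") from exc
    values = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return ExpressionTable(sample_ids, gene_ids, values, drug_of_sample)


def read_gct(path: str | Path) -> ExpressionTable:
    """Read a GCT 1.3 file (or the two-line-header TSV dialect).

    The GCT is genes x samples with no row metadata and a single column
    metadata row ``pert_iname``; the returned table is transposed to
    samples x genes.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise GctFormatError(f"{path}: empty file")
    if lines[0].startswith("#1.3"):
        if len(lines) < 4:
            raise GctFormatError(f"{path}: truncated GCT")
        dims = lines[1].split("\t")
        if len(dims) != 4:
            raise GctFormatError(f"{path}: GCT dimension line must have 4 fields, got {len(dims)}")
        try:
            n_genes, n_samples, n_rmeta, n_cmeta = (int(v) for v in dims)
        except ValueError as exc:
            raise GctFormatError(f"{path}: non-integer GCT dimensions") from exc
        if n_rmeta != 0 or n_cmeta != 1:
            raise GctFormatError(
                f"{path}: this dialect expects 0 row-metadata / 1 column-metadata fields, "
                f"got {n_rmeta}/{n_cmeta}"
            )
        table = _parse_body(lines[2:], str(path))
        if table.shape != (n_samples, n_genes):
            raise GctFormatError(
                f"{path}: header declares {n_genes} genes x {n_samples} samples, "
                f"body has {table.shape[1]} x {table.shape[0]}"
            )
        return table
    return _parse_body(lines, str(path))


def write_gct(table: ExpressionTable, path: str | Path) -> None:
    """Write an :class:`ExpressionTable` as GCT 1.3 (genes x samples)."""
    path = Path(path)
    n_samples, n_genes = table.shape
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{n_genes}\t{n_samples}\t0\t1\n")
        fh.write("id\t" + "\t".join(table.sample_ids) + "\n")
        fh.write(
            "pert_iname\t"
            + "\t".join(table.drug_of_sample[s] for s in table.sample_ids)
            + "\n"
        )
        for j, gene in enumerate(table.gene_ids):
            vals = "\t".join(repr(float(v)) for v in table.values[:, j])
            fh.write(f"{gene}\t{vals}\n")


def read_label_table(path: str | Path) -> dict[str, set[str]]:
    """Read a drug -> first-level-ATC-letters table.

    TSV rows of ``drug_id<TAB>letters`` with semicolon-separated letters from
    the 14-letter ATC alphabet. Multi-label drugs keep every label.
    """
    labels: dict[str, set[str]] = {}
    valid = set(ATC_LETTERS)
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.rstrip("\n")
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'drug<TAB>letters', got {ln!r}")
        drug, letters_field = parts
        letters = {tok.strip() for tok in letters_field.split(";") if tok.strip()}
        if not letters:
            raise ValueError(f"{path}:{lineno}: drug {drug!r} has an empty label set")
        unknown = letters - valid
        if unknown:
            raise ValueError(
                f"{path}:{lineno}: unknown ATC letter(s) {sorted(unknown)} for drug {drug!r}"
            )
        if drug in labels:
            raise ValueError(f"{path}:{lineno}: duplicate drug {drug!r}")
        labels[drug] = letters
    return labels


def write_label_table(labels: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in labels:
            fh.write(f"{drug}\t{';'.join(sorted(labels[drug]))}\n")


def read_feature_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a drug -> item-id set table (side-effect terms or fingerprint bits).

    TSV rows of ``drug_id<TAB>item_id``; a drug listed with an empty second
    field records an empty set.
    """
    sets: dict[str, set[str]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.rstrip("\n")
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'drug<TAB>item', got {ln!r}")
        drug, item = parts
        sets.setdefault(drug, set())
        if item:
            sets[drug].add(item)
    return sets


def write_feature_sets(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in sets:
            items = sorted(sets[drug])
            if not items:
                fh.write(f"{drug}\t\n")
            for item in items:
                fh.write(f"{drug}\t{item}\n")


def write_matrix(df: pd.DataFrame, path: str | Path, decimals: int = 6) -> None:
    """Write a labelled matrix as TSV with ``decimals``-digit floats."""
    df.to_csv(path, sep="\t", float_format=f"%.{decimals}f")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
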