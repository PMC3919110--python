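"""Readers and writers for expression matrices, sample designs and probe annotations.

The expression matrix is a probes x samples table of log2-scale intensities
(RMA-style normalized values). Two on-disk dialects are supported: plain TSV
(header row of sample ids, first column probe ids) and the GEO series-matrix
text dialect, of which only the delimited table block is parsed.

Missing values ("null" or blank cells) are kept as NaN and handled pairwise
downstream: a sample only contributes to a pair if both probes have a value.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: strings treated as missing values on read
NA_STRINGS = ("", "null", "NULL", "NA", "NaN")

SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 intensities.

    ``data`` is indexed by probe id (rows) and sample id (columns); missing
    entries are NaN, all other entries are finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = self.data.to_numpy(dtype=float, copy=False)
        bad = np.isinf(values)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-finite value at probe {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values_for(self, probe_id: str, sample_ids=None) -> np.ndarray:
        """Row of intensities for one probe, optionally restricted to samples."""
        row = self.data.loc[probe_id]
        if sample_ids is not None:
            row = row.loc[list(sample_ids)]
        return row.to_numpy(dtype=float)


@dataclass
class ConditionDesign:
    """Assignment of each sample to exactly one condition label."""

    assignments: dict[str, str]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label)
        return list(seen)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == condition]

    def counts(self) -> dict[str, int]:
        return {c: len(self.samples_in(c)) for c in self.conditions}

    def validate_two_conditions(self) -> None:
        labels = self.conditions
        if len(labels) != 2:
            raise ValidationError(
                f"differential analysis needs exactly 2 conditions, "
                f"got {len(labels)}: {sorted(labels)}"
            )

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = sorted(set(self.assignments) - set(matrix.sample_ids))
        if missing:
            raise ValidationError(
                f"design samples absent from matrix: {missing[:5]}"
            )


@dataclass
class ProbeAnnotation:
    """Probe -> gene mapping; probes may map to several genes and vice versa."""

    mapping: dict[str, frozenset[str]]
    _gene_index: dict[str, tuple[str, ...]] = field(
        default=None, repr=False, compare=False
    )

    def genes_for(self, probe_id: str) -> frozenset[str]:
        return self.mapping.get(probe_id, frozenset())

    def probes_for(self, gene_id: str) -> tuple[str, ...]:
        if self._gene_index is None:
            index: dict[str, list[str]] = {}
            for probe, genes in self.mapping.items():
                for gene in genes:
                    index.setdefault(gene, []).append(probe)
            self._gene_index = {g: tuple(ps) for g, ps in index.items()}
        return self._gene_index.get(gene_id, ())

    def __len__(self) -> int:
        return len(self.mapping)


def _frame_to_matrix(df: pd.DataFrame, origin: str) -> ExpressionMatrix:
    """Convert a raw string table to a validated ExpressionMatrix."""
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() & ~df.astype(str).isin(NA_STRINGS)
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise FormatError(
            f"{origin}: non-numeric cell {df.iat[i, j]!r} at "
            f"probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def _parse_table_text(text: str, origin: str) -> pd.DataFrame:
    header = text.splitlines()[0].split("\t")[1:]
    header = [h.strip('"') for h in header]
    seen: set[str] = set()
    for sample in header:
        if sample in seen:
            raise FormatError(f"{origin}: duplicate sample id: {sample!r}")
        seen.add(sample)
    df = pd.read_csv(
        io.StringIO(text), sep="\t", index_col=0, dtype=str,
        na_values=list(NA_STRINGS), keep_default_na=False,
    )
    df.columns = header  # undo pandas' mangling of duplicate names
    return df


def read_matrix(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from ``path``.

    dialect="tsv": header row of sample ids, first column probe ids.
    dialect="series_matrix": GEO series-matrix text; only the block between
    the standard begin/end marker lines is parsed, metadata lines ignored.
    """
    with open(path, encoding="utf-8") as handle:
        text = handle.read()
    if dialect == "series_matrix":
        lines = text.splitlines()
        try:
            start = next(
                i for i, ln in enumerate(lines)
                if ln.strip().lower() == SERIES_MATRIX_BEGIN
            )
            end = next(
                i for i, ln in enumerate(lines)
                if ln.strip().lower() == SERIES_MATRIX_END
            )
        except StopIteration:
            raise FormatError(
                f"{path}: series-matrix table markers not found"
            ) from None
        text = "\n".join(lines[start + 1:end])
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    return _frame_to_matrix(_parse_table_text(text, str(path)), str(path))


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write TSV that ``read_matrix`` round-trips exactly (NaN as 'null')."""
    matrix.data.to_csv(path, sep="\t", na_rep="null", index_label="ID_REF")


def read_design(path, require_two_conditions: bool = True) -> ConditionDesign:
    """Read a two-column sample_id/condition table (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    if df.empty:
        raise ValidationError(f"{path}: no samples")
    sample_col, cond_col = df.columns[:2]
    dup = df[sample_col][df[sample_col].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate sample id: {dup.iloc[0]!r}")
    design = ConditionDesign(
        dict(zip(df[sample_col], df[cond_col]))
    )
    if require_two_conditions:
        design.validate_two_conditions()
    for cond, n in design.counts().items():
        logger.info("condition %s: %d samples", cond, n)
    return design


def write_design(design: ConditionDesign, path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.assignments),
         "condition": list(design.assignments.values())}
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> ProbeAnnotation:
    """Read a two-column probe_id/gene_id table; repeated probes accumulate genes.

    Rows with an empty gene field are skipped with a warning (Affymetrix
    control probes carry no gene).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns, got {df.shape[1]}")
    probe_col, gene_col = df.columns[:2]
    mapping: dict[str, set[str]] = {}
    n_skipped = 0
    for probe, gene in zip(df[probe_col], df[gene_col]):
        gene = gene.strip()
        if not gene or gene in NA_STRINGS:
            n_skipped += 1
            continue
        mapping.setdefault(probe, set()).add(gene)
    if n_skipped:
        logger.warning(
            "%s: skipped %d rows with empty gene annotation", path, n_skipped
        )
    return ProbeAnnotation({p: frozenset(g) for p, g in mapping.items()})


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    rows = [
        (probe, gene)
        for probe, genes in annotation.mapping.items()
        for gene in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["probe_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
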