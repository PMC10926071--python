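"""Reading, probe collapsing and group annotation of expression matrices.

Supports two text dialects: plain TSV (features in rows, samples in
columns, first row sample ids, first column feature ids) and the GEO
series-matrix dialect (only the block between the standard
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers is
parsed). Platform annotation is a GPL-style TSV mapping probe ids to gene
symbols; multi-symbol cells (``A /// B``) may be expanded or dropped.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical disease-stage groups, in severity order
GROUPS = ("healthy", "incipient", "moderate", "severe")


@dataclass
class RawExpressionSet:
    """Probe-level expression: probes x samples."""

    values: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate probe ids: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleAnnotation:
    """Per-sample disease-stage group plus optional clinical covariates."""

    groups: pd.Series  # sample id -> group name
    covariates: pd.DataFrame | None = None  # e.g. ntf, braak, mmse

    def __post_init__(self) -> None:
        bad = sorted(set(self.groups.unique()) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown groups {bad}; expected subset of {GROUPS}")

    def group_counts(self) -> dict[str, int]:
        counts = self.groups.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS if counts.get(g, 0)}


@dataclass
class ExpressionMatrix:
    """Gene-level expression (genes x samples) with optional group labels."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    annotation: SampleAnnotation | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> pd.Series | None:
        if self.annotation is None:
            return None
        return self.annotation.groups.reindex(self.values.columns)

    def group_counts(self) -> dict[str, int]:
        groups = self.groups
        if groups is None:
            raise ValueError("no sample annotation attached")
        counts = groups.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS if counts.get(g, 0)}


def _parse_table(text: str, source: str) -> pd.DataFrame:
    """Parse a TSV block: first row sample ids, first column feature ids."""
    buf = io.StringIO(text)
    try:
        df = pd.read_csv(buf, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed header / ragged rows
        raise ValueError(f"{source}: malformed table: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{source}: malformed header (no sample columns)")
    df.index = df.index.astype(str).str.strip().str.strip('"')
    df.columns = df.columns.astype(str).str.strip().str.strip('"')
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].str.strip().str.strip('"'), errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{source}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        out[col] = converted
    return out


def read_expression(path: str, dialect: str = "tsv") -> RawExpressionSet:
    """Read a probe/gene x sample expression table.

    Parameters
    ----------
    path:
        Input file.
    dialect:
        ``"tsv"`` for a plain tab-separated table, ``"series_matrix"``
        for the GEO series-matrix dialect.
    """
    if dialect not in ("tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        text = fh.read()
    if dialect == "series_matrix":
        lines = text.splitlines()
        try:
            start = next(
                i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin")
            )
            end = next(
                i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end")
            )
        except StopIteration:
            raise ValueError(f"{path}: series-matrix table markers not found") from None
        text = "\n".join(lines[start + 1 : end])
    values = _parse_table(text, path)
    raw = RawExpressionSet(values)
    logger.info("read %d features x %d samples from %s", *raw.shape, path)
    return raw


def read_probe_map(
    path: str,
    probe_col: str = "ID",
    symbol_col: str = "Gene Symbol",
) -> dict[str, list[str]]:
    """Read a GPL-style annotation TSV into probe -> [gene symbols].

    Multi-symbol cells separated by ``///`` are split; empty symbols mean
    the probe is unmapped and the probe is omitted from the map.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in (probe_col, symbol_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: dict[str, list[str]] = {}
    for probe, cell in zip(df[probe_col], df[symbol_col]):
        if pd.isna(cell):
            continue
        symbols = [s.strip() for s in str(cell).split("///")]
        symbols = [s for s in symbols if s]
        if symbols:
            out[str(probe).strip()] = symbols
    return out


def read_sample_annotation(path: str) -> SampleAnnotation:
    """Read a sample annotation TSV (sample_id, group, optional covariates)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.set_index("sample_id")
    groups = df["group"].str.strip().str.lower()
    cov_cols = [c for c in df.columns if c != "group"]
    covariates = df[cov_cols].apply(pd.to_numeric, errors="coerce") if cov_cols else None
    return SampleAnnotation(groups=groups, covariates=covariates)


def collapse_probes(
    raw: RawExpressionSet,
    probe_map: dict[str, list[str]],
    ambiguous: str = "expand",
) -> ExpressionMatrix:
    """Collapse probe rows to gene rows by averaging.

    Each gene row is the arithmetic mean of the rows of every probe
    annotated to it. Probes absent from the map are dropped (count
    logged). ``ambiguous="expand"`` assigns multi-symbol probes to every
    listed gene; ``"drop"`` discards them.
    """
    if ambiguous not in ("expand", "drop"):
        raise ValueError(f"unknown ambiguous policy {ambiguous!r}")
    assignments: list[tuple[str, str]] = []  # (gene, probe)
    unmapped = 0
    for probe in raw.probe_ids:
        symbols = probe_map.get(probe)
        if not symbols:
            unmapped += 1
            continue
        if len(symbols) > 1 and ambiguous == "drop":
            continue
        for gene in symbols:
            assignments.append((gene, probe))
    if not assignments:
        raise ValueError("no probe maps to any gene")
    logger.info("dropped %d unmapped probes", unmapped)
    frame = pd.DataFrame(assignments, columns=["gene", "probe"])
    collapsed = (
        raw.values.loc[frame["probe"].to_numpy()]
        .set_axis(frame["gene"].to_numpy(), axis=0)
        .groupby(level=0, sort=True)
        .mean()
    )
    return ExpressionMatrix(values=collapsed)


def attach_groups(expr: ExpressionMatrix, ann: SampleAnnotation) -> ExpressionMatrix:
    """Attach group labels, requiring every expression sample to be annotated."""
    missing = [s for s in expr.sample_ids if s not in ann.groups.index]
    if missing:
        raise ValueError(f"samples missing from annotation: {missing}")
    extra = [s for s in ann.groups.index if s not in expr.sample_ids]
    if extra:
        logger.warning("annotation has %d samples not in the matrix; ignored", len(extra))
    sub = SampleAnnotation(
        groups=ann.groups.reindex(expr.sample_ids),
        covariates=None
        if ann.covariates is None
        else ann.covariates.reindex(expr.sample_ids),
    )
    return ExpressionMatrix(values=expr.values, annotation=sub)


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    """Write a gene-level matrix as canonical TSV (deterministic order)."""
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_gene_matrix(path: str) -> ExpressionMatrix:
    """Read back a matrix written by :func:`write_expression`."""
    raw = read_expression(path, dialect="tsv")
    return ExpressionMatrix(values=raw.values)
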