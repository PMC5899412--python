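"""Reading and writing expression time series, candidate networks and result tables.

Expression data arrives either as a delimited matrix (one header row of time
values, one gene per row) or as the table section of a GEO SOFT file.
Candidate regulations arrive as a two-column regulator/target TSV or as a
Cytoscape SIF edge list.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: cell contents treated as missing on import
DEFAULT_NA_TOKENS = ("", "NA", "NaN", "nan", "null", "NULL")


@dataclass(frozen=True)
class TimeGrid:
    """Ordered measurement times t_1 < ... < t_N (units are the user's)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("a time grid needs at least 3 time points")
        if not np.all(np.isfinite(t)):
            raise ValueError("time values must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times not increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class ExpressionSet:
    """Genes x time-points expression matrix with explicit time coordinates.

    ``values`` holds NaN at missing cells; ``missing_mask`` mirrors that so
    downstream code never has to guess which NaNs are deliberate.
    """

    gene_ids: list[str]
    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != len(set(self.gene_ids)):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), self.grid.n):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.grid.n} time points"
            )
        present = ~np.isnan(self.values)
        if not np.all(np.isfinite(self.values[present])):
            raise ValueError("non-finite expression values")
        neg = self.values < 0
        if np.any(neg):
            warnings.warn(
                f"clipped {int(neg.sum())} negative expression values to 0 "
                "(transcript levels are non-negative)",
                stacklevel=2,
            )
            self.values = np.where(neg, 0.0, self.values)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id: {gene_id!r}") from None
        return self.values[i]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.grid.times)


@dataclass
class CandidateNetwork:
    """Directed candidate regulations as (regulator, target) pairs, in file order."""

    edges: list[tuple[str, str]]
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        if not self.allow_self_loops:
            loops = [e for e in self.edges if e[0] == e[1]]
            if loops:
                raise ValueError(f"self-loop edges not allowed: {loops}")

    @property
    def regulators(self) -> list[str]:
        seen: dict[str, None] = {}
        for r, _ in self.edges:
            seen.setdefault(r)
        return list(seen)

    def resolve(self, dataset: ExpressionSet) -> None:
        """Raise KeyError if any edge references a gene absent from *dataset*."""
        known = set(dataset.gene_ids)
        missing = sorted({g for e in self.edges for g in e if g not in known})
        if missing:
            raise KeyError(f"network references unknown gene ids: {missing}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g


#: stable column order for result tables
RESULT_COLUMNS = [
    "regulator",
    "target",
    "label",
    "fit_quality",
    "residual_ss",
    "regularization",
    "k1",
    "k2",
    "b",
    "w",
    "note",
    "provenance",
]


def empty_result_table() -> pd.DataFrame:
    return pd.DataFrame(columns=RESULT_COLUMNS)


def _sniff_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in ("\t", ",", ";")}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else "\t"


def read_delimited(
    path: str | Path,
    *,
    delimiter: str | None = None,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> ExpressionSet:
    """Read a genes x time matrix with a header row of time values.

    The delimiter is autodetected among tab/comma/semicolon unless given.
    The first header field may be a label (e.g. "gene") and is skipped when
    it does not parse as a number.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = delimiter or _sniff_delimiter(lines[0])
    header = lines[0].split(delim)
    try:
        float(header[0])
        time_fields = header
        label_offset = 0
    except ValueError:
        time_fields = header[1:]
        label_offset = 1
    try:
        times = np.array([float(f) for f in time_fields])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric time in header: {exc}") from None
    grid = TimeGrid(times)  # raises "times not increasing" on bad order

    na = set(na_tokens)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(delim)
        if label_offset == 0:
            raise ValueError(f"{path}: header has no gene-id column")
        gene_ids.append(fields[0].strip())
        cells = fields[1:]
        if len(cells) != grid.n:
            raise ValueError(
                f"{path}:{lineno}: expected {grid.n} values, got {len(cells)}"
            )
        rows.append(
            [np.nan if c.strip() in na else float(c) for c in cells]
        )
    return ExpressionSet(gene_ids, np.array(rows, dtype=float), grid)


def write_delimited(
    dataset: ExpressionSet,
    path: str | Path,
    *,
    delimiter: str = "\t",
    float_fmt: str = "%.17g",
) -> None:
    """Write an expression set so that ``read_delimited`` round-trips it."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("gene" + delimiter)
        fh.write(delimiter.join(float_fmt % t for t in dataset.grid.times))
        fh.write("\n")
        for gid, row in zip(dataset.gene_ids, dataset.values):
            cells = ["" if np.isnan(v) else float_fmt % v for v in row]
            fh.write(gid + delimiter + delimiter.join(cells) + "\n")


def read_soft(
    path: str | Path,
    *,
    sample_times: Mapping[str, float] | None = None,
) -> ExpressionSet:
    """Read the table section of a GEO SOFT file (GDS or series-matrix-like GSE).

    Only the expression table is consumed: an ID_REF column, an optional
    IDENTIFIER column and one column per sample. When *sample_times* is not
    given, samples are mapped to consecutive unit-spaced time points in
    column order — this is logged prominently since the time axis then
    carries no physical units.

    Literal ``null`` cells (GEO's missing-value token) become missing.
    """
    path = Path(path)
    begin_tags = ("!dataset_table_begin", "!series_matrix_table_begin")
    end_tags = ("!dataset_table_end", "!series_matrix_table_end")
    table_lines: list[str] = []
    in_table = False
    saw_delims = False
    with path.open() as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            low = stripped.strip().lower()
            if low in begin_tags:
                in_table, saw_delims = True, True
                continue
            if low in end_tags:
                in_table = False
                continue
            if in_table and stripped.strip():
                table_lines.append(stripped)
    if not saw_delims or not table_lines:
        raise ValueError(f"{path}: no SOFT table section (missing table delimiters)")

    header = table_lines[0].split("\t")
    ncol_meta = 2 if len(header) > 1 and header[1].upper() == "IDENTIFIER" else 1
    sample_cols = header[ncol_meta:]
    if not sample_cols:
        raise ValueError(f"{path}: SOFT table has no sample columns")

    if sample_times is not None:
        unknown = sorted(set(sample_times) - set(sample_cols))
        if unknown:
            raise ValueError(
                f"sample mapping references unknown columns: {unknown}"
            )
        keep = [c for c in sample_cols if c in sample_times]
        if not keep:
            raise ValueError("sample mapping matches no SOFT table column")
        order = sorted(keep, key=lambda c: sample_times[c])
        times = np.array([sample_times[c] for c in order])
    else:
        order = list(sample_cols)
        times = np.arange(len(sample_cols), dtype=float)
        logger.warning(
            "no sample->time mapping supplied for %s: using column order with "
            "unit spacing (time axis has arbitrary units)",
            path.name,
        )

    col_idx = {c: i for i, c in enumerate(sample_cols)}
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    na = set(DEFAULT_NA_TOKENS)
    for line in table_lines[1:]:
        fields = line.split("\t")
        gene_ids.append(fields[0].strip())
        cells = fields[ncol_meta:]
        row = []
        for c in order:
            i = col_idx[c]
            tok = cells[i].strip() if i < len(cells) else ""
            row.append(np.nan if tok in na else float(tok))
        rows.append(row)
    return ExpressionSet(gene_ids, np.array(rows, dtype=float), TimeGrid(times))


def read_network(path: str | Path, format: str | None = None) -> CandidateNetwork:
    """Read a candidate network from a two-column TSV or a SIF edge list.

    The format is inferred from the extension when not given (``.sif`` vs
    anything else). SIF lines are ``source interaction target [target ...]``;
    each target yields one edge. Duplicate edges are dropped with a warning.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown network format: {format!r}")

    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if format == "sif":
                if len(tokens) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF line needs source, interaction "
                        f"and at least one target, got {len(tokens)} tokens"
                    )
                edges.extend((tokens[0], t) for t in tokens[2:])
            else:
                if len(tokens) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected two columns (regulator, target)"
                    )
                edges.append((tokens[0], tokens[1]))
    if not edges:
        raise ValueError(f"{path}: no edges")

    seen: dict[tuple[str, str], None] = {}
    dupes = 0
    for e in edges:
        if e in seen:
            dupes += 1
        seen.setdefault(e)
    if dupes:
        logger.warning("%s: dropped %d duplicate edge(s)", path.name, dupes)
    return CandidateNetwork(list(seen))


def write_results(
    table: pd.DataFrame, path: str | Path, *, float_precision: int = 6
) -> None:
    """Write a result table as TSV with a stable column order.

    Output is byte-identical for identical input (floats fixed to
    *float_precision* significant digits).
    """
    out = table.reindex(columns=RESULT_COLUMNS)
    out.to_csv(
        Path(path),
        sep="\t",
        index=False,
        float_format=f"%.{float_precision}g",
        lineterminator="\n",
    )


def read_overrides(path: str | Path) -> pd.DataFrame:
    """Read a manual-decision TSV: regulator, target, new_label (header optional)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("overrides file needs 3 columns: regulator, target, new_label")
    df = df.iloc[:, :3]
    df.columns = ["regulator", "target", "new_label"]
    if df.iloc[0].tolist() == ["regulator", "target", "new_label"]:
        df = df.iloc[1:].reset_index(drop=True)
    return df
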