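"""File formats and containers for placebo-controlled paired expression trials.

Everything downstream works with two validated containers — an
:class:`ExpressionMatrix` (genes × samples) and :class:`TrialMetadata`
(per-sample annotation plus per-subject lung-function endpoints) — together
with two community formats: GMT gene-set collections and tab-separated
interaction-network edge lists (HumanNet-style ``gene_a<TAB>gene_b<TAB>weight``).

All files are UTF-8, tab-delimited, with a header row; lines starting with
``#`` are treated as comments (the pipeline uses them to stamp outputs with
the configuration hash).

Graph semantics are undirected and unweighted by default: reversed duplicate
edges collapse to a single edge, self-loops are discarded with a logged
count, and edge weights are parsed and retained as metadata but ignored by
shortest-path computations.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ARMS = ("case", "control")
TIMEPOINTS = ("pre", "post")

METADATA_COLUMNS = ("sample_id", "subject_id", "arm", "timepoint", "fev1_pre", "fev1_post")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violates its invariants."""


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression values, genes (rows) × samples (columns).

    Values are floats on whatever normalized (typically log) scale the
    experiment produced; NaN marks a missing measurement.  Duplicate gene or
    sample identifiers are rejected at construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        dup_g = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_g:
            raise ValidationError(f"duplicate gene ids: {sorted(map(str, dup_g))}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {sorted(map(str, dup_s))}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise ValidationError("expression matrix contains non-numeric columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(samples)])

    def complete_genes(self) -> tuple["ExpressionMatrix", int]:
        """Drop genes with any missing value (logged), per the NaN policy."""
        mask = self.data.notna().all(axis=1)
        n_dropped = int((~mask).sum())
        if n_dropped:
            log.info("excluding %d genes with missing values", n_dropped)
        return ExpressionMatrix(self.data.loc[mask]), n_dropped


def _read_table_lines(path: str | Path) -> tuple[list[str], list[int]]:
    """Non-comment, non-blank lines of a TSV plus their 1-based file line numbers."""
    lines: list[str] = []
    numbers: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lines.append(line)
            numbers.append(i)
    if not lines:
        raise FormatError(f"{path}: empty file")
    return lines, numbers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV (first column gene id, header of sample ids).

    Ragged rows, non-numeric cells and duplicate identifiers raise
    :class:`FormatError` naming the offending line.
    """
    lines, numbers = _read_table_lines(path)
    width = lines[0].count("\t")
    if width == 0:
        raise FormatError(f"{path}: header has a single column; expected tab-separated sample ids")
    for line, lineno in zip(lines[1:], numbers[1:]):
        n_fields = line.count("\t") + 1
        if n_fields != width + 1:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({n_fields} fields, expected {width + 1})"
            )
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    bad_cols = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad_cols:
        col = bad_cols[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
        pos = df.index.get_loc(bad_rows[0])
        raise FormatError(
            f"{path}:{numbers[1 + pos]}: non-numeric value {df[col].iloc[pos]!r} "
            f"in sample column {col!r} (gene {bad_rows[0]!r})"
        )
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicate gene ids: {dup}")
    return ExpressionMatrix(df.astype(float))


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, header_meta: Mapping[str, str] | None = None
) -> None:
    _write_with_meta(matrix.data, path, header_meta, index_label="gene")


def _write_with_meta(
    df: pd.DataFrame,
    path: str | Path,
    header_meta: Mapping[str, str] | None,
    index_label: str | None = None,
    index: bool = True,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}={value}\n")
        # %.17g guarantees bit-exact float round trips through the TSV
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, float_format="%.17g")


# ---------------------------------------------------------------------------
# trial metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialMetadata:
    """Per-sample trial annotation: subject, arm, timepoint and FEV1 endpoints.

    FEV1 (forced expiratory volume in one second) pre/post values are carried
    per subject and repeated on each of the subject's sample rows; they may be
    NaN for subjects without spirometry.
    """

    samples: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        df = self.samples
        required = {"subject_id", "arm", "timepoint", "fev1_pre", "fev1_post"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate sample ids: {dup}")
        bad_arm = sorted(set(df["arm"]) - set(ARMS))
        if bad_arm:
            raise ValidationError(f"unknown arm labels {bad_arm}; expected {ARMS}")
        bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise ValidationError(f"unknown timepoints {bad_tp}; expected {TIMEPOINTS}")
        counts = df.groupby(["subject_id", "timepoint"], observed=True).size()
        over = counts[counts > 1]
        if len(over):
            subj, tp = over.index[0]
            raise ValidationError(f"subject {subj!r} has {over.iloc[0]} {tp!r} samples")
        arms_per_subject = df.groupby("subject_id")["arm"].nunique()
        mixed = arms_per_subject[arms_per_subject > 1].index.tolist()
        if mixed:
            raise ValidationError(f"subjects assigned to more than one arm: {mixed}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def subjects(self, arm: str | None = None) -> list[str]:
        df = self.samples if arm is None else self.samples[self.samples["arm"] == arm]
        return sorted(df["subject_id"].unique())

    def paired_subjects(self, arm: str | None = None) -> list[str]:
        """Subjects with both a pre and a post sample (optionally within an arm)."""
        df = self.samples if arm is None else self.samples[self.samples["arm"] == arm]
        tp = df.groupby("subject_id")["timepoint"].agg(set)
        return sorted(tp[tp.apply(lambda s: {"pre", "post"} <= s)].index)

    def sample_id(self, subject: str, timepoint: str) -> str | None:
        df = self.samples
        hit = df.index[(df["subject_id"] == subject) & (df["timepoint"] == timepoint)]
        return None if len(hit) == 0 else hit[0]

    def samples_for(self, arm: str | None = None, timepoint: str | None = None) -> list[str]:
        df = self.samples
        if arm is not None:
            df = df[df["arm"] == arm]
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return list(df.index)

    def arm_of(self, subject: str) -> str:
        rows = self.samples[self.samples["subject_id"] == subject]
        if rows.empty:
            raise ValidationError(f"unknown subject {subject!r}")
        return rows["arm"].iloc[0]

    def fev1(self) -> pd.DataFrame:
        """Per-subject frame with columns arm, fev1_pre, fev1_post."""
        df = self.samples.groupby("subject_id").agg(
            arm=("arm", "first"), fev1_pre=("fev1_pre", "first"), fev1_post=("fev1_post", "first")
        )
        return df


def read_metadata(path: str | Path) -> TrialMetadata:
    lines, numbers = _read_table_lines(path)
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep="\t", dtype={"sample_id": str, "subject_id": str}, float_precision="round_trip")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    df = df.set_index("sample_id")
    try:
        return TrialMetadata(df)
    except ValidationError as err:
        raise FormatError(f"{path}: {err}") from err


def write_metadata(
    meta: TrialMetadata, path: str | Path, header_meta: Mapping[str, str] | None = None
) -> None:
    _write_with_meta(meta.samples, path, header_meta, index_label="sample_id")


@dataclass(frozen=True)
class AlignmentReport:
    matrix_only: tuple[str, ...]
    metadata_only: tuple[str, ...]


def align_samples(
    matrix: ExpressionMatrix, meta: TrialMetadata
) -> tuple[ExpressionMatrix, TrialMetadata, AlignmentReport]:
    """Intersect matrix and metadata samples, reporting every dropped id.

    Samples present on one side only are removed from both containers and
    listed in the returned :class:`AlignmentReport`; nothing is dropped
    silently.
    """
    mat_ids = set(matrix.sample_ids)
    meta_ids = set(meta.sample_ids)
    shared = [s for s in matrix.sample_ids if s in meta_ids]
    if not shared:
        raise ValidationError("matrix and metadata share no sample ids")
    report = AlignmentReport(
        matrix_only=tuple(sorted(mat_ids - meta_ids)),
        metadata_only=tuple(sorted(meta_ids - mat_ids)),
    )
    if report.matrix_only:
        log.warning("samples only in matrix (dropped): %s", list(report.matrix_only))
    if report.metadata_only:
        log.warning("samples only in metadata (dropped): %s", list(report.metadata_only))
    return (
        matrix.subset_samples(shared),
        TrialMetadata(meta.samples.loc[shared]),
        report,
    )


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    lines, numbers = _read_table_lines(path)
    collection: dict[str, GeneSet] = {}
    for line, lineno in zip(lines, numbers):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line has {len(fields)} fields; expected >=3 "
                "(name, description, at least one gene)"
            )
        name, description, *genes = fields
        genes = [g for g in genes if g]
        if name in collection:
            raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        collection[name] = GeneSet(name, description, frozenset(genes))
    return collection


def write_gmt(collection: Mapping[str, GeneSet] | Iterable[GeneSet], path: str | Path) -> None:
    sets = collection.values() if isinstance(collection, Mapping) else collection
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def flag_unknown_genes(genes: Iterable[str], matrix: ExpressionMatrix, what: str) -> set[str]:
    """Genes referenced by a GMT/network but absent from the matrix (kept, logged)."""
    unknown = set(genes) - set(matrix.gene_ids)
    if unknown:
        log.info("%s references %d genes not in the expression matrix", what, len(unknown))
    return unknown


# ---------------------------------------------------------------------------
# interaction-network edge lists
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> nx.Graph:
    """Read an undirected interaction network from a TSV edge list.

    Accepts 2- or 3-column rows (``gene_a  gene_b  [weight]``) with or without
    a header line.  Reversed duplicates collapse to one undirected edge (first
    weight kept); self-loops are dropped with a logged count.
    """
    lines, numbers = _read_table_lines(path)
    start = 0
    first = lines[0].split("\t")
    if first[0].strip().lower() in {"gene_a", "source", "node1", "genea"}:
        start = 1
    graph = nx.Graph()
    n_self = n_dup = 0
    for line, lineno in zip(lines[start:], numbers[start:]):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: edge row needs >=2 fields")
        a, b = fields[0], fields[1]
        weight = 1.0
        if len(fields) >= 3 and fields[2]:
            try:
                weight = float(fields[2])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from err
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b, weight=weight)
    if n_self:
        log.info("dropped %d self-loop edges", n_self)
    if n_dup:
        log.info("collapsed %d duplicate/reversed edges", n_dup)
    return graph


def write_network(
    graph: nx.Graph, path: str | Path, header_meta: Mapping[str, str] | None = None
) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "weight": data.get("weight", 1.0)}
        for a, b, data in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    _write_with_meta(df, path, header_meta, index=False)


# ---------------------------------------------------------------------------
# plain gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; ``#`` comments and blanks ignored; order kept."""
    lines, _ = _read_table_lines(path)
    genes: list[str] = []
    for line in lines:
        gene = line.split("\t")[0].strip()
        if gene and gene not in genes:
            genes.append(gene)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")
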