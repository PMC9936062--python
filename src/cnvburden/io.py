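"""Readers and writers for the plain-text tables the pipeline exchanges.

Every format is tab-separated UTF-8 with LF line endings; lines starting
with ``#`` are comments.  Readers raise :class:`FormatError` naming the
offending line for malformed input; every writer produces a file its paired
reader parses back to an equal in-memory value.

Formats
-------
depth.tsv       header ``sample<TAB>chrom:start-end ...``, one row per sample
calls.tsv       columns SAMPLE CHROM START END TYPE QUAL NTARGETS
labels.tsv      columns SAMPLE GROUP with GROUP in {CASE, CONTROL}
*.bed           BED3+1: chrom start end name-or-type
ppi.edges       two whitespace-separated node names per line, undirected
expr.tsv        genes x conditions matrix, first column ``gene``
lengths.tsv     columns CHROM LENGTH
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .intervals import CnvType, GenomicInterval, IntervalError, TypedInterval

__all__ = [
    "FormatError",
    "DepthMatrix",
    "CnvCall",
    "CALL_COLUMNS",
    "read_depth_matrix",
    "write_depth_matrix",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_labels",
    "write_labels",
    "read_gene_bed",
    "read_region_bed",
    "read_typed_bed",
    "write_bed",
    "read_chrom_lengths",
    "read_edge_list",
    "write_edge_list",
    "read_expression_tsv",
    "write_expression_tsv",
]

CALL_COLUMNS = ["SAMPLE", "CHROM", "START", "END", "TYPE", "QUAL", "NTARGETS"]


class FormatError(ValueError):
    """A file violated one of the formats documented in this module."""


@dataclass
class DepthMatrix:
    """Mean read depth per sample (rows) per exon target (columns)."""

    sample_ids: list[str]
    targets: list[GenomicInterval]
    values: np.ndarray  # (n_samples, n_targets), non-negative floats

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.targets)):
            raise FormatError(
                f"depth matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.targets)} targets"
            )
        if self.values.size and self.values.min() < 0:
            raise FormatError("depth matrix contains negative values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class CnvCall:
    """One sample's called deletion or duplication event."""

    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    quality: float
    n_targets: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "cnv_type", CnvType(self.cnv_type))
        if self.quality < 0:
            raise FormatError(f"negative quality on call {self}")
        if self.n_targets < 1:
            raise FormatError(f"n_targets must be >= 1 on call {self}")

    @property
    def typed(self) -> TypedInterval:
        return TypedInterval(self.interval, self.cnv_type)


def _parse_target_label(label: str, where: str) -> GenomicInterval:
    try:
        chrom, span = label.split(":")
        start_s, end_s = span.split("-")
        return GenomicInterval(chrom, int(start_s), int(end_s))
    except (ValueError, IntervalError) as exc:
        raise FormatError(f"{where}: bad target label {label!r}: {exc}") from exc


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_depth_matrix(path: str | Path) -> DepthMatrix:
    """Parse a depth TSV: header of ``chrom:start-end`` labels, row per sample."""
    rows: list[list[float]] = []
    sample_ids: list[str] = []
    targets: list[GenomicInterval] | None = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if targets is None:
            targets = [
                _parse_target_label(lab, f"{path}:{lineno}") for lab in fields[1:]
            ]
            continue
        if len(fields) != len(targets) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(targets) + 1} fields, "
                f"found {len(fields)}"
            )
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric depth: {exc}") from exc
        if any(v < 0 for v in values):
            raise FormatError(f"{path}:{lineno}: negative depth value")
        sample_ids.append(fields[0])
        rows.append(values)
    if targets is None:
        raise FormatError(f"{path}: empty depth matrix (no header)")
    return DepthMatrix(sample_ids, targets, np.array(rows, dtype=float))


def write_depth_matrix(dm: DepthMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "sample\t" + "\t".join(str(t) for t in dm.targets) + "\n"
        )
        for sid, row in zip(dm.sample_ids, dm.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def calls_to_frame(calls: Iterable[CnvCall]) -> pd.DataFrame:
    """Tabular view of a call list with the documented column order."""
    records = [
        (
            c.sample_id,
            c.interval.chrom,
            c.interval.start,
            c.interval.end,
            c.cnv_type.value,
            c.quality,
            c.n_targets,
        )
        for c in calls
    ]
    return pd.DataFrame(records, columns=CALL_COLUMNS)


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    calls: list[CnvCall] = []
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_seen:
            if fields != CALL_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected header {CALL_COLUMNS}, got {fields}"
                )
            header_seen = True
            continue
        if len(fields) != len(CALL_COLUMNS):
            raise FormatError(
                f"{path}:{lineno}: expected {len(CALL_COLUMNS)} fields"
            )
        sample, chrom, start, end, ctype, qual, ntarg = fields
        if ctype not in CnvType.__members__:
            raise FormatError(
                f"{path}:{lineno}: TYPE must be DEL or DUP, got {ctype!r}"
            )
        try:
            calls.append(
                CnvCall(
                    sample,
                    GenomicInterval(chrom, int(start), int(end)),
                    CnvType(ctype),
                    float(qual),
                    int(ntarg),
                )
            )
        except (ValueError, IntervalError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not header_seen:
        raise FormatError(f"{path}: missing header line")
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.interval.chrom}\t{c.interval.start}\t"
                f"{c.interval.end}\t{c.cnv_type.value}\t{c.quality:g}\t"
                f"{c.n_targets}\n"
            )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read sample -> CASE/CONTROL labels."""
    labels: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields == ["SAMPLE", "GROUP"]:
            continue
        if len(fields) != 2 or fields[1] not in ("CASE", "CONTROL"):
            raise FormatError(
                f"{path}:{lineno}: expected 'SAMPLE<TAB>CASE|CONTROL'"
            )
        labels[fields[0]] = fields[1]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("SAMPLE\tGROUP\n")
        for sid, grp in labels.items():
            fh.write(f"{sid}\t{grp}\n")


def _read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out: list[tuple[GenomicInterval, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected >= 4 BED columns")
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
        except (ValueError, IntervalError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        out.append((iv, fields[3]))
    return out


def read_gene_bed(path: str | Path) -> dict[str, GenomicInterval]:
    """BED3+name gene annotation; duplicate gene names are an error."""
    genes: dict[str, GenomicInterval] = {}
    for iv, name in _read_bed(path):
        if name in genes:
            raise FormatError(f"{path}: duplicate gene name {name!r}")
        genes[name] = iv
    return genes


def read_region_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    """BED3+name curated regions (e.g. known pathogenic loci)."""
    return _read_bed(path)


def read_typed_bed(path: str | Path) -> list[TypedInterval]:
    """BED3+type reference map (e.g. a common-CNV catalogue)."""
    out = []
    for iv, name in _read_bed(path):
        if name not in CnvType.__members__:
            raise FormatError(
                f"{path}: 4th column must be DEL or DUP, got {name!r}"
            )
        out.append(TypedInterval(iv, CnvType(name)))
    return out


def write_bed(
    records: Iterable[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for iv, name in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields == ["CHROM", "LENGTH"]:
            continue
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'CHROM<TAB>LENGTH'")
        try:
            lengths[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return lengths


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("CHROM\tLENGTH\n")
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Undirected edge list; duplicates (in either order) deduplicated,
    self-loops dropped with a warning."""
    seen: set[frozenset[str]] = set()
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected two node names")
        a, b = fields
        if a == b:
            warnings.warn(
                f"{path}:{lineno}: dropping self-loop edge {a!r}", stacklevel=2
            )
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        edges.append((a, b))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Genes x conditions expression matrix with a ``gene`` index column."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene name {dup!r}")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative expression value")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")
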