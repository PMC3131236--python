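"""On-disk formats: BED reads, annotation / expression / plate TSVs, result JSON.

All genomic coordinates are 0-based half-open internally.  BED is native to
that convention; annotation readers must declare whether their TSS column is
0- or 1-based.  Chromosome names are compared after stripping an optional
``chr`` prefix so mixed-source inputs join correctly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

_ALLOSOMES = {"X", "Y"}


class ParseError(ValueError):
    """Malformed record in an input file (message names the offending line)."""


class SchemaError(ValueError):
    """Input table does not match its declared schema."""


def norm_chrom(chrom: str) -> str:
    """Normalise a chromosome name by stripping an optional ``chr`` prefix."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: identity, TSS (0-based), strand, chromosome."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def is_allosome(self) -> bool:
        return norm_chrom(self.chrom).upper() in _ALLOSOMES


@dataclass
class ReadSet:
    """One ChIP library: mark label plus mapped read intervals (0-based half-open)."""

    mark: str
    reads: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.reads:
            if start >= end:
                raise ValueError(f"read ({chrom},{start},{end}): start must be < end")

    @property
    def library_size(self) -> int:
        return len(self.reads)

    def __add__(self, other: "ReadSet") -> "ReadSet":
        """Pool two libraries (e.g. a cell mixture); marks must agree."""
        if other.mark != self.mark:
            raise ValueError(f"cannot pool marks {self.mark!r} and {other.mark!r}")
        return ReadSet(self.mark, self.reads + other.reads)


def read_bed(path: str | Path, mark: str | None = None) -> ReadSet:
    """Read a BED3+ file of mapped reads into a :class:`ReadSet`.

    The mark label is taken from ``mark`` or, failing that, the file stem.
    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    """
    path = Path(path)
    reads: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            reads.append((chrom, start, end))
    return ReadSet(mark=mark if mark is not None else path.stem, reads=reads)


def write_bed(readset: ReadSet, path: str | Path) -> None:
    """Write a ReadSet as BED3; round-trips coordinates bit-exactly."""
    with open(path, "w") as fh:
        for chrom, start, end in readset.reads:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_annotation(path: str | Path, one_based: bool | None = None) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with columns gene_id, chrom, tss, strand.

    The TSS coordinate convention is declared either with the ``one_based``
    argument or by a header comment line ``# coords: 1-based`` / ``0-based``.
    1-based positions are converted to the internal 0-based convention.
    """
    path = Path(path)
    declared: bool | None = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "1-based" in first:
                declared = True
            elif "0-based" in first:
                declared = False
    if one_based is None:
        if declared is None:
            raise SchemaError(
                f"{path}: TSS coordinate convention undeclared; pass one_based= or add "
                "a '# coords: 1-based' / '# coords: 0-based' header line"
            )
        one_based = declared

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(f"{path}: duplicate gene_id(s): {sorted(set(dupes))}")

    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.tss) - 1 if one_based else int(row.tss)
        genes.append(GeneAnnotation(str(row.gene_id), str(row.chrom), tss, str(row.strand)))
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write annotation as TSV with a 0-based header declaration."""
    with open(path, "w") as fh:
        fh.write("# coords: 0-based\n")
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: type = str
    required: bool = True
    default: object = None


def read_table(
    path: str | Path,
    schema: Sequence[ColumnSpec],
    na_policy: str = "drop",
) -> pd.DataFrame:
    """Read a TSV against a declared schema; returns typed rows.

    ``na_policy``: ``drop`` excludes rows with NA in a required numeric column
    (logged), ``error`` raises.  Missing optional columns are filled with
    their declared defaults.
    """
    if na_policy not in ("drop", "error"):
        raise ValueError(f"na_policy must be 'drop' or 'error', got {na_policy!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in schema:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(f"{path}: missing required column {col.name!r}")
            df[col.name] = col.default
    for col in schema:
        if col.dtype in (float, int):
            coerced = pd.to_numeric(df[col.name], errors="coerce")
            bad = coerced.isna() & df[col.name].notna()
            na = coerced.isna()
            if na.any():
                if na_policy == "error":
                    idx = int(na.idxmax())
                    raise ParseError(
                        f"{path}: non-numeric or missing value in column "
                        f"{col.name!r} at data row {idx}"
                    )
                logger.info(
                    "%s: dropping %d row(s) with NA/non-numeric %r (%d unparseable)",
                    path, int(na.sum()), col.name, int(bad.sum()),
                )
                df = df[~na].copy()
                coerced = coerced[~na]
            df[col.name] = coerced.astype(col.dtype)
    return df.reset_index(drop=True)


EXPRESSION_SCHEMA = (
    ColumnSpec("gene_id", str),
    ColumnSpec("expression", float),
    ColumnSpec("expressed", str, required=False, default=None),
)


def read_expression(path: str | Path, na_policy: str = "drop") -> pd.DataFrame:
    """Read a per-gene expression TSV (gene_id, expression[, expressed]).

    Expression values must be non-negative; gene_id unique.  The optional
    ``expressed`` column (true/false) marks the platform's detection call.
    """
    df = read_table(path, EXPRESSION_SCHEMA, na_policy=na_policy)
    if (df["expression"] < 0).any():
        raise ParseError(f"{path}: negative expression value")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(f"{path}: duplicate gene_id(s): {sorted(set(dupes))}")
    if df["expressed"].notna().any():
        df["expressed"] = df["expressed"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes") if v is not None else None
        )
    return df


QPCR_SCHEMA = (
    ColumnSpec("sample", str),
    ColumnSpec("amplicon", str),
    ColumnSpec("channel", str),
    ColumnSpec("replicate", int),
    ColumnSpec("ct", float),
)

SINGLE_CELL_SCHEMA = (
    ColumnSpec("well_id", str),
    ColumnSpec("control_call", str),
    ColumnSpec("target_call", str),
)


def write_json(obj: Mapping, path: str | Path) -> None:
    """Write a result object as JSON with an embedded schema-version field."""
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    try:
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with a schema-version header comment."""
    with open(path, "w") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)
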