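"""Typed readers and writers for the tabular artifacts of the pipeline.

Every structure the pipeline touches — junction count matrices, expression
matrices, sample attributes, clinical tables, PSI tables, gene sets and
titration tables — is read into a validated in-memory container here, and
written back in a bit-stable TSV/JSON dialect (fixed column order, tab
separator, ``.`` decimal point, ``NA`` for missing values).

Conventions
-----------
* Junction identifiers are ``chrom:start-end`` with 1-based inclusive
  coordinates, the GTEx junction-file convention; ``start < end`` is enforced.
* Parsers never silently coerce: every dropped or modified row is counted in
  the :class:`ParseReport` attached to the returned object.
* When matrices are joined to attribute tables elsewhere in the package the
  sample *intersection* is used and unmatched samples are reported, not fatal.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_JUNCTION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")

__all__ = [
    "FormatError",
    "ValidationError",
    "ParseReport",
    "JunctionCountMatrix",
    "ExpressionMatrix",
    "SampleAttributes",
    "ClinicalTable",
    "GeneSetCollection",
    "TitrationCurve",
    "parse_junction_id",
    "read_junction_counts",
    "read_expression_matrix",
    "read_sample_attributes",
    "read_clinical_table",
    "read_psi_table",
    "read_gene_sets",
    "read_rbp_list",
    "read_titration",
    "write_table",
]


class FormatError(ValueError):
    """File does not match the expected layout (missing header, columns...)."""


class ValidationError(ValueError):
    """File parsed but the content violates a container invariant."""


@dataclass
class ParseReport:
    """Audit trail of a parse: nothing is dropped or changed silently."""

    n_rows_read: int = 0
    n_rows_kept: int = 0
    dropped: list[str] = field(default_factory=list)
    modified: list[str] = field(default_factory=list)

    def drop(self, reason: str) -> None:
        self.dropped.append(reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def parse_junction_id(junction_id: str) -> tuple[str, int, int]:
    """Split ``chrom:start-end`` into components; reject malformed ids.

    Coordinates are 1-based with inclusive ends and must satisfy
    ``start < end``.
    """
    m = _JUNCTION_RE.match(junction_id)
    if m is None:
        raise ValidationError(
            f"malformed junction id {junction_id!r}; expected 'chrom:start-end'"
        )
    start, end = int(m.group("start")), int(m.group("end"))
    if start >= end:
        raise ValidationError(
            f"junction {junction_id!r}: start must be < end (got {start} >= {end})"
        )
    return m.group("chrom"), start, end


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class JunctionCountMatrix:
    """Raw split-read counts, junctions x samples, with gene assignment."""

    junction_ids: list[str]
    gene_of_junction: dict[str, str]
    sample_ids: list[str]
    counts: np.ndarray
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.junction_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({len(self.junction_ids)}, {len(self.sample_ids)})"
            )
        if len(set(self.junction_ids)) != len(self.junction_ids):
            raise ValidationError("duplicate junction ids")
        if np.any(self.counts < 0):
            j, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at junction {self.junction_ids[j]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        for jid in self.junction_ids:
            parse_junction_id(jid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.junction_ids, columns=self.sample_ids)
        df.insert(0, "gene", [self.gene_of_junction.get(j, "NA") for j in self.junction_ids])
        df.index.name = "junction_id"
        return df


@dataclass
class ExpressionMatrix:
    """Gene expression values, genes x samples.

    ``normalized`` records whether depth normalization has been applied;
    ``unit`` records the declared input unit (the readers are unit-agnostic).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False
    unit: str = "counts"
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if np.any(self.values < 0):
            raise ValidationError("negative expression values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_vector(self, gene: str) -> pd.Series:
        if gene not in self.gene_ids:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        row = self.values[self.gene_ids.index(gene)]
        return pd.Series(row, index=self.sample_ids, name=gene)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene"
        return df


@dataclass
class SampleAttributes:
    """Sample -> tissue / condition mapping plus free-form covariates."""

    table: pd.DataFrame  # index sample_id, columns tissue, condition, ...
    report: ParseReport = field(default_factory=ParseReport)

    VALID_CONDITIONS = frozenset({"normal", "tumor", "NA"})

    def __post_init__(self) -> None:
        if "tissue" not in self.table.columns:
            raise ValidationError("sample attributes need a 'tissue' column")
        if "condition" not in self.table.columns:
            self.table = self.table.assign(condition="NA")
        bad = set(self.table["condition"]) - self.VALID_CONDITIONS
        if bad:
            raise ValidationError(f"invalid condition labels: {sorted(bad)}")
        if (self.table["tissue"].astype(str).str.len() == 0).any():
            raise ValidationError("empty tissue label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def tissue_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "tissue"])

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return list(self.table.index[self.table["tissue"] == tissue])


@dataclass
class ClinicalTable:
    """Per-patient survival record: time in days and a 0/1 death flag."""

    table: pd.DataFrame  # columns patient_id, time_days, event, [covariates]
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        for col in ("patient_id", "time_days", "event"):
            if col not in self.table.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        ev = set(pd.unique(self.table["event"]))
        if not ev <= {0, 1}:
            raise ValidationError(f"event values outside {{0,1}}: {sorted(ev - {0, 1})}")
        if (self.table["time_days"] <= 0).any():
            raise ValidationError("non-positive time_days survived validation")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (two-column TSV or GMT)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class TitrationCurve:
    """One binding titration: (protein concentration nmol/L, bound fraction)."""

    probe_name: str
    conc: np.ndarray  # nmol/L
    bound_frac: np.ndarray  # in [0, 1] after reported clipping
    replicate_id: str = "rep1"
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.bound_frac = np.asarray(self.bound_frac, dtype=float)
        if self.conc.shape != self.bound_frac.shape:
            raise ValidationError("conc and bound_frac length mismatch")
        if np.any(self.conc < 0):
            raise ValidationError("negative protein concentration")
        out = (self.bound_frac < 0) | (self.bound_frac > 1)
        if out.any():
            self.report.modified.append(
                f"{int(out.sum())} bound fractions clipped to [0, 1]"
            )
            self.bound_frac = np.clip(self.bound_frac, 0.0, 1.0)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", header=0, dtype=str, na_values=["NA"],
                           keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, no header") from exc


def read_junction_counts(path: str | Path, dialect: str = "generic_tsv") -> JunctionCountMatrix:
    """Read a junction x sample count table.

    ``generic_tsv``: columns ``junction_id`` (``chrom:start-end``), ``gene``,
    then one column per sample.  ``gtex_like``: first two columns are the
    junction name with underscore-separated coordinates (``chrom_start_end``)
    and the gene, as in GTEx junction-count exports.
    """
    if dialect not in ("generic_tsv", "gtex_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need junction, gene and >=1 sample column")
    id_col, gene_col = df.columns[0], df.columns[1]
    sample_ids = list(df.columns[2:])

    junction_ids: list[str] = []
    for raw in df[id_col]:
        jid = str(raw)
        if dialect == "gtex_like":
            parts = jid.split("_")
            if len(parts) != 3:
                raise ValidationError(f"malformed GTEx junction id {jid!r}")
            jid = f"{parts[0]}:{parts[1]}-{parts[2]}"
        junction_ids.append(jid)

    counts = np.empty((len(df), len(sample_ids)), dtype=np.int64)
    for si, s in enumerate(sample_ids):
        col = pd.to_numeric(df[s], errors="coerce")
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise ValidationError(
                f"non-numeric count at junction {junction_ids[row]!r}, sample {s!r}"
            )
        if (col % 1 != 0).any():
            row = int((col % 1 != 0).idxmax())
            raise ValidationError(
                f"non-integer count at junction {junction_ids[row]!r}, sample {s!r}"
            )
        if (col < 0).any():
            row = int((col < 0).idxmax())
            raise ValidationError(
                f"negative count at junction {junction_ids[row]!r}, sample {s!r}"
            )
        counts[:, si] = col.astype(np.int64)

    report = ParseReport(n_rows_read=len(df), n_rows_kept=len(df))
    gene_map = dict(zip(junction_ids, df[gene_col].astype(str)))
    return JunctionCountMatrix(junction_ids, gene_map, sample_ids, counts, report)


def read_expression_matrix(path: str | Path, unit: str = "counts") -> ExpressionMatrix:
    """Read a gene x sample expression table (first column = gene id)."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need gene column and >=1 sample column")
    gene_ids = [str(g) for g in df.iloc[:, 0]]
    sample_ids = list(df.columns[1:])
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(f"{path}: non-numeric expression value")
    report = ParseReport(n_rows_read=len(df), n_rows_kept=len(df))
    return ExpressionMatrix(gene_ids, sample_ids, values, normalized=False,
                            unit=unit, report=report)


def read_sample_attributes(path: str | Path) -> SampleAttributes:
    """Read sample attributes: columns sample_id, tissue, [condition, ...]."""
    df = _read_tsv(path)
    if "sample_id" not in df.columns or "tissue" not in df.columns:
        raise FormatError(f"{path}: need sample_id and tissue columns")
    df = df.set_index("sample_id")
    df["condition"] = df.get("condition", pd.Series("NA", index=df.index)).fillna("NA")
    report = ParseReport(n_rows_read=len(df), n_rows_kept=len(df))
    return SampleAttributes(df, report)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read clinical outcomes; rows with non-positive time are dropped and
    counted in the parse report (with a logged warning)."""
    df = _read_tsv(path)
    for col in ("patient_id", "time_days", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: clinical table missing column {col!r}")
    report = ParseReport(n_rows_read=len(df))
    df = df.copy()
    df["time_days"] = pd.to_numeric(df["time_days"], errors="raise").astype(float)
    event = pd.to_numeric(df["event"], errors="raise")
    if not set(pd.unique(event)) <= {0, 1}:
        bad = sorted(set(pd.unique(event)) - {0, 1})
        raise ValidationError(f"{path}: event values outside {{0,1}}: {bad}")
    df["event"] = event.astype(int)
    keep = df["time_days"] > 0
    if (~keep).any():
        for pid in df.loc[~keep, "patient_id"]:
            report.drop(f"patient {pid!r}: non-positive time_days")
        logger.warning("%s: dropped %d rows with non-positive time_days",
                       path, int((~keep).sum()))
    df = df.loc[keep].reset_index(drop=True)
    report.n_rows_kept = len(df)
    return ClinicalTable(df, report)


def read_psi_table(path: str | Path) -> pd.DataFrame:
    """Read an event x sample PSI table (percent scale, NA allowed).

    Returns a DataFrame indexed by event_id with one column per sample.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need event column and >=1 sample column")
    df = df.set_index(df.columns[0])
    df.index.name = "event_id"
    out = df.apply(pd.to_numeric, errors="coerce")
    valid = out.to_numpy(dtype=float)
    in_range = np.isnan(valid) | ((valid >= 0) & (valid <= 100))
    if not in_range.all():
        raise ValidationError(f"{path}: PSI values outside [0, 100]")
    return out


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets from two-column TSV (set_name, gene) or GMT."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    text = path.read_text(encoding="utf-8").rstrip("\n")
    if not text:
        raise FormatError(f"{path}: empty gene set file")
    lines = text.split("\n")
    if path.suffix.lower() == ".gmt":
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: GMT line needs name, description, >=1 gene")
            name, desc, genes = fields[0], fields[1], fields[2:]
            sets.setdefault(name, set()).update(g for g in genes if g)
            descriptions[name] = desc
    else:
        start = 1 if lines[0].lower().startswith("set_name") else 0
        for ln in lines[start:]:
            fields = ln.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: expected two columns (set_name, gene)")
            sets.setdefault(fields[0], set()).add(fields[1])
    return GeneSetCollection(sets, descriptions)


def read_rbp_list(path: str | Path) -> list[str]:
    """Read an RBP symbol list, one symbol per line (RBPDB-style export)."""
    path = Path(path)
    symbols = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()]
    symbols = [s for s in symbols if s and not s.startswith("#")]
    if not symbols:
        raise FormatError(f"{path}: no RBP symbols found")
    return symbols


def read_titration(path: str | Path) -> list[TitrationCurve]:
    """Read titration TSV with columns probe, replicate, conc_nM, bound_frac."""
    df = _read_tsv(path)
    for col in ("probe", "replicate", "conc_nM", "bound_frac"):
        if col not in df.columns:
            raise FormatError(f"{path}: titration table missing column {col!r}")
    curves = []
    for (probe, rep), grp in df.groupby(["probe", "replicate"], sort=True):
        curves.append(TitrationCurve(
            probe_name=str(probe),
            conc=pd.to_numeric(grp["conc_nM"]).to_numpy(),
            bound_frac=pd.to_numeric(grp["bound_frac"]).to_numpy(),
            replicate_id=str(rep),
        ))
    return curves


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _frame_of(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    if isinstance(table, (JunctionCountMatrix, ExpressionMatrix)):
        return table.to_frame().reset_index()
    if isinstance(table, (ClinicalTable,)):
        return table.table
    if isinstance(table, SampleAttributes):
        return table.table.reset_index()
    raise TypeError(f"cannot serialize object of type {type(table).__name__}")


def write_table(table, path: str | Path, format: str = "tsv") -> None:
    """Write a typed table bit-stably: fixed column order, tab separator,
    ``.`` decimal point, ``NA`` for missing, no locale dependence."""
    path = Path(path)
    if format == "tsv":
        df = _frame_of(table)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", lineterminator="\n")
    elif format == "json":
        df = _frame_of(table)
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=1, sort_keys=False) + "\n",
                        encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")
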