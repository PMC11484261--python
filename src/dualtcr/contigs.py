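"""Reading and writing single-cell V(D)J contig annotation tables.

Two dialects are supported:

* ``tenx_csv`` — the 10x Genomics ``filtered_contig_annotations.csv`` layout
  (one row per assembled contig, comma separated, QC flags as ``True``/``False``
  strings).
* ``airr_tsv`` — the AIRR Community Rearrangement schema (tab separated;
  ``cell_id``, ``locus``, ``v_call`` ... column names).

Both are normalized into :class:`ContigRecord` lists.  Gene calls have IMGT
allele suffixes (``*01``) stripped at read time because all downstream analyses
operate at gene-segment resolution.  ``sample_id`` is injected by the caller:
per-sample files from public repositories carry no sample column, and barcode
suffixes are not a reliable sample key.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import SchemaError

Dialect = Literal["tenx_csv", "airr_tsv"]

#: Minimum columns a 10x contig CSV must provide.
TENX_REQUIRED = (
    "barcode",
    "is_cell",
    "high_confidence",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3_nt",
    "productive",
    "umis",
)

#: Minimum columns an AIRR rearrangement TSV must provide.
AIRR_REQUIRED = (
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "productive",
    "duplicate_count",
)

_TRUE = {"true"}
_FALSE = {"false"}
_NONE_PRODUCTIVE = {"none", "", "na", "non", "nan"}


@dataclass(frozen=True, slots=True)
class ContigRecord:
    """One assembled V(D)J contig with its QC flags and gene calls.

    ``productive`` is tri-state: ``True`` (in-frame, stop-free), ``False``
    (non-productive), or ``None`` (the assembler could not decide).
    """

    barcode: str
    contig_id: str
    is_cell: bool
    high_confidence: bool
    chain: str
    v_gene: str | None
    d_gene: str | None
    j_gene: str | None
    c_gene: str | None
    cdr3_aa: str | None
    cdr3_nt: str | None
    productive: bool | None
    umis: int
    reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if not self.barcode:
            raise SchemaError("contig has an empty barcode")
        if not self.contig_id:
            raise SchemaError("contig has an empty contig_id")
        if self.umis < 0 or self.reads < 0:
            raise SchemaError(
                f"contig {self.contig_id}: negative umis/reads ({self.umis}/{self.reads})"
            )


def strip_allele(gene: str | None) -> str | None:
    """Drop an IMGT allele suffix: ``TRBV20-1*01`` -> ``TRBV20-1``."""
    if gene is None:
        return None
    return gene.split("*", 1)[0]


def _opt_str(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"none", "nan"}:
        return None
    return s


def _parse_bool(value: object, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise SchemaError(f"row {row}: cannot parse {column}={value!r} as a boolean")


def _parse_productive(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE or s == "t":  # AIRR spells booleans T/F
        return True
    if s in _FALSE or s == "f":
        return False
    if s in _NONE_PRODUCTIVE:
        return None
    raise SchemaError(f"cannot parse productive={value!r}")


def _parse_count(value: object, column: str, row: int) -> int:
    try:
        n = int(float(value))
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: cannot parse {column}={value!r} as an integer")
    if n < 0:
        raise SchemaError(f"row {row}: negative {column}={n}")
    return n


def _require_columns(df: pd.DataFrame, required: Iterable[str], dialect: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{dialect} input is missing required column(s): {', '.join(missing)}"
        )


def read_contigs(
    path: str | Path | _io.IOBase,
    dialect: Dialect = "tenx_csv",
    sample_id: str = "",
) -> list[ContigRecord]:
    """Read a contig annotation table into normalized :class:`ContigRecord`s.

    Extra columns are tolerated (cellranger versions differ); only the
    dialect's minimum column set is required.  Row order is preserved.

    Parameters
    ----------
    path
        File path or open text handle.
    dialect
        ``tenx_csv`` or ``airr_tsv``.
    sample_id
        Sample label stamped onto every record.

    Raises
    ------
    SchemaError
        If a required column is absent or a row cannot be parsed; the message
        names the column / row number (1-based, excluding the header).
    """
    if dialect == "tenx_csv":
        df = pd.read_csv(path, sep=",", dtype=str, keep_default_na=False)
        _require_columns(df, TENX_REQUIRED, "tenx_csv")
        return _records_from_tenx(df, sample_id)
    if dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        _require_columns(df, AIRR_REQUIRED, "airr_tsv")
        return _records_from_airr(df, sample_id)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _records_from_tenx(df: pd.DataFrame, sample_id: str) -> list[ContigRecord]:
    records: list[ContigRecord] = []
    has = df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(has, row))
        records.append(
            ContigRecord(
                barcode=str(r["barcode"]).strip(),
                contig_id=_opt_str(r.get("contig_id")) or f"{r['barcode']}_contig_{i}",
                is_cell=_parse_bool(r["is_cell"], "is_cell", i),
                high_confidence=_parse_bool(r["high_confidence"], "high_confidence", i),
                chain=str(r["chain"]).strip(),
                v_gene=strip_allele(_opt_str(r.get("v_gene"))),
                d_gene=strip_allele(_opt_str(r.get("d_gene"))),
                j_gene=strip_allele(_opt_str(r.get("j_gene"))),
                c_gene=strip_allele(_opt_str(r.get("c_gene"))),
                cdr3_aa=_opt_str(r.get("cdr3")),
                cdr3_nt=_opt_str(r.get("cdr3_nt")),
                productive=_parse_productive(r["productive"]),
                umis=_parse_count(r["umis"], "umis", i),
                reads=_parse_count(r.get("reads", 0), "reads", i),
                sample_id=sample_id,
            )
        )
    return records


def _records_from_airr(df: pd.DataFrame, sample_id: str) -> list[ContigRecord]:
    records: list[ContigRecord] = []
    has = df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(has, row))
        # AIRR has no is_cell / high_confidence; rearrangements in a
        # filtered AIRR file are presumed cell-associated and confident.
        records.append(
            ContigRecord(
                barcode=str(r["cell_id"]).strip(),
                contig_id=_opt_str(r.get("sequence_id")) or f"{r['cell_id']}_seq_{i}",
                is_cell=True,
                high_confidence=True,
                chain=str(r["locus"]).strip(),
                v_gene=strip_allele(_opt_str(r.get("v_call"))),
                d_gene=strip_allele(_opt_str(r.get("d_call"))),
                j_gene=strip_allele(_opt_str(r.get("j_call"))),
                c_gene=strip_allele(_opt_str(r.get("c_call"))),
                cdr3_aa=_opt_str(r.get("junction_aa")),
                cdr3_nt=_opt_str(r.get("junction")),
                productive=_parse_productive(r["productive"]),
                umis=_parse_count(r["duplicate_count"], "duplicate_count", i),
                reads=_parse_count(r.get("consensus_count", 0), "consensus_count", i),
                sample_id=sample_id,
            )
        )
    return records


_TENX_COLUMNS = (
    "barcode",
    "is_cell",
    "contig_id",
    "high_confidence",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "full_length",
    "productive",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
)

_AIRR_COLUMNS = (
    "cell_id",
    "sequence_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "junction",
    "junction_aa",
    "productive",
    "duplicate_count",
    "consensus_count",
)


def _fmt_productive(p: bool | None, dialect: Dialect) -> str:
    if p is None:
        return "None" if dialect == "tenx_csv" else ""
    if dialect == "tenx_csv":
        return "True" if p else "False"
    return "T" if p else "F"


def contigs_to_frame(records: Sequence[ContigRecord], dialect: Dialect) -> pd.DataFrame:
    """Render records as a DataFrame in the given dialect's column layout."""
    if dialect == "tenx_csv":
        rows = [
            {
                "barcode": r.barcode,
                "is_cell": str(r.is_cell),
                "contig_id": r.contig_id,
                "high_confidence": str(r.high_confidence),
                "chain": r.chain,
                "v_gene": r.v_gene or "None",
                "d_gene": r.d_gene or "None",
                "j_gene": r.j_gene or "None",
                "c_gene": r.c_gene or "None",
                "full_length": "True",
                "productive": _fmt_productive(r.productive, dialect),
                "cdr3": r.cdr3_aa or "None",
                "cdr3_nt": r.cdr3_nt or "None",
                "reads": r.reads,
                "umis": r.umis,
            }
            for r in records
        ]
        return pd.DataFrame(rows, columns=list(_TENX_COLUMNS))
    if dialect == "airr_tsv":
        rows = [
            {
                "cell_id": r.barcode,
                "sequence_id": r.contig_id,
                "locus": r.chain,
                "v_call": r.v_gene or "",
                "d_call": r.d_gene or "",
                "j_call": r.j_gene or "",
                "c_call": r.c_gene or "",
                "junction": r.cdr3_nt or "",
                "junction_aa": r.cdr3_aa or "",
                "productive": _fmt_productive(r.productive, dialect),
                "duplicate_count": r.umis,
                "consensus_count": r.reads,
            }
            for r in records
        ]
        return pd.DataFrame(rows, columns=list(_AIRR_COLUMNS))
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_contigs(
    records: Sequence[ContigRecord],
    path: str | Path | _io.IOBase,
    dialect: Dialect = "tenx_csv",
) -> None:
    """Write records in the given dialect.

    Round trip: ``read_contigs(write_contigs(x))`` reproduces ``x`` on every
    field the dialect supports.  The AIRR dialect does not carry ``is_cell``
    or ``high_confidence`` (they read back as ``True``), and neither dialect
    stores ``sample_id`` (re-injected by the caller on read).
    """
    frame = contigs_to_frame(records, dialect)
    sep = "," if dialect == "tenx_csv" else "\t"
    frame.to_csv(path, sep=sep, index=False)
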