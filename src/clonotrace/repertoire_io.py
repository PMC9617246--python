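"""Reading, QC filtering, and per-cell chain pairing of V(D)J contig tables.

Supports the 10x ``filtered_contig_annotations.csv`` dialect and the AIRR
Rearrangement TSV dialect.  Filtering retains high-confidence, productive
contigs with sufficient UMI support; pairing keeps cells with exactly one
heavy + one light chain (BCR) or exactly one alpha + one beta chain (TCR).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_LOCI = frozenset({"IGH", "IGK", "IGL", "TRA", "TRB"})
BCR_LOCI = frozenset({"IGH", "IGK", "IGL"})
TCR_LOCI = frozenset({"TRA", "TRB"})


class ContigFormatError(ValueError):
    """Raised when a contig table is missing required columns."""


class ContigRowError(ValueError):
    """Raised when a single row cannot be parsed; carries the row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled V(D)J contig for one chain of one cell."""

    barcode: str
    contig_id: str
    locus: str
    v_call: str
    j_call: str
    junction_nt: str
    junction_aa: str = ""
    c_call: str = ""
    umis: int = 0
    reads: int = 0
    productive: bool = False
    high_confidence: bool = False
    sequence_alignment: str | None = None
    germline_alignment: str | None = None

    def __post_init__(self) -> None:
        if self.locus not in VALID_LOCI:
            raise ValueError(f"invalid locus {self.locus!r}; expected one of {sorted(VALID_LOCI)}")
        if self.umis < 0:
            raise ValueError("umis must be non-negative")
        if self.reads < 0:
            raise ValueError("reads must be non-negative")
        if self.junction_nt and self.junction_aa:
            if len(self.junction_nt) != 3 * len(self.junction_aa):
                raise ValueError(
                    "junction_nt length must be 3x junction_aa length "
                    f"({len(self.junction_nt)} vs {len(self.junction_aa)})"
                )
        if self.sequence_alignment is not None and self.germline_alignment is not None:
            if len(self.sequence_alignment) != len(self.germline_alignment):
                raise ValueError("sequence_alignment and germline_alignment lengths differ")


@dataclass(frozen=True)
class CellChainSet:
    """The retained chains of one cell after pairing."""

    barcode: str
    receptor_type: str  # "BCR" or "TCR"
    chains: tuple[ContigRecord, ...]

    @property
    def heavy(self) -> ContigRecord:
        """Heavy (IGH) or beta (TRB) chain."""
        locus = "IGH" if self.receptor_type == "BCR" else "TRB"
        return next(c for c in self.chains if c.locus == locus)

    @property
    def light(self) -> ContigRecord:
        """Light (IGK/IGL) or alpha (TRA) chain."""
        loci = {"IGK", "IGL"} if self.receptor_type == "BCR" else {"TRA"}
        return next(c for c in self.chains if c.locus in loci)


_TEN_X_REQUIRED = ("barcode", "chain", "v_gene", "j_gene", "umis", "productive", "high_confidence")
_AIRR_REQUIRED = ("cell_id", "locus", "v_call", "j_call", "junction", "duplicate_count", "productive")

_TRUE_TOKENS = {"true", "t", "1", "yes"}
_FALSE_TOKENS = {"false", "f", "0", "no", "none", ""}


def _parse_bool(value: str, row_index: int, column: str) -> bool:
    token = value.strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ContigRowError(row_index, f"unparseable boolean {value!r} in column {column!r}")


def _parse_int(value: str, row_index: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ContigRowError(row_index, f"unparseable integer {value!r} in column {column!r}") from None


def read_contigs(path, dialect: str = "10x-contig-csv") -> list[ContigRecord]:
    """Read a contig annotation table into a list of :class:`ContigRecord`.

    Parameters
    ----------
    path
        Path to the table.
    dialect
        ``"10x-contig-csv"`` (comma-separated, 10x column names) or
        ``"airr-tsv"`` (tab-separated, AIRR Rearrangement column names).

    Raises
    ------
    ContigFormatError
        If a required column is absent.
    ContigRowError
        If a boolean or integer field fails to parse, with the row index.
    """
    if dialect == "10x-contig-csv":
        return _read_10x(path)
    if dialect == "airr-tsv":
        return _read_airr(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _check_columns(fieldnames: Sequence[str] | None, required: Sequence[str], where: str) -> None:
    present = set(fieldnames or ())
    for col in required:
        if col not in present:
            raise ContigFormatError(f"{where}: missing required column {col!r}")


def _read_10x(path) -> list[ContigRecord]:
    records: list[ContigRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle)
        _check_columns(reader.fieldnames, _TEN_X_REQUIRED, "10x contig CSV")
        for i, row in enumerate(reader):
            locus = row["chain"].strip()
            if locus not in VALID_LOCI:
                # 10x emits "Multi"/"None" for ambiguous contigs; treat as invalid
                logger.warning("row %d: unsupported chain %r, contig skipped", i, locus)
                continue
            records.append(
                ContigRecord(
                    barcode=row["barcode"],
                    contig_id=row.get("contig_id", f"contig_{i}"),
                    locus=locus,
                    v_call=row["v_gene"],
                    j_call=row["j_gene"],
                    c_call=row.get("c_gene", "") or "",
                    junction_nt=row.get("cdr3_nt", "") or "",
                    junction_aa=row.get("cdr3", "") or "",
                    umis=_parse_int(row["umis"], i, "umis"),
                    reads=_parse_int(row.get("reads", "0") or "0", i, "reads"),
                    productive=_parse_bool(row["productive"], i, "productive"),
                    high_confidence=_parse_bool(row["high_confidence"], i, "high_confidence"),
                )
            )
    return records


def _read_airr(path) -> list[ContigRecord]:
    records: list[ContigRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        _check_columns(reader.fieldnames, _AIRR_REQUIRED, "AIRR TSV")
        for i, row in enumerate(reader):
            locus = row["locus"].strip()
            if locus not in VALID_LOCI:
                logger.warning("row %d: unsupported locus %r, contig skipped", i, locus)
                continue
            seq_aln = row.get("sequence_alignment") or None
            germ_aln = row.get("germline_alignment") or None
            records.append(
                ContigRecord(
                    barcode=row["cell_id"],
                    contig_id=row.get("sequence_id", f"contig_{i}"),
                    locus=locus,
                    v_call=row["v_call"],
                    j_call=row["j_call"],
                    c_call=row.get("c_call", "") or "",
                    junction_nt=row.get("junction", "") or "",
                    junction_aa=row.get("junction_aa", "") or "",
                    umis=_parse_int(row["duplicate_count"], i, "duplicate_count"),
                    reads=_parse_int(row.get("consensus_count", "0") or "0", i, "consensus_count"),
                    productive=_parse_bool(row["productive"], i, "productive"),
                    high_confidence=_parse_bool(row.get("high_confidence", "T"), i, "high_confidence"),
                    sequence_alignment=seq_aln,
                    germline_alignment=germ_aln,
                )
            )
    return records


def write_contigs(records: Iterable[ContigRecord], path, dialect: str = "10x-contig-csv") -> None:
    """Write records back out in the given dialect (inverse of :func:`read_contigs`)."""
    records = list(records)
    if dialect == "10x-contig-csv":
        cols = ["barcode", "contig_id", "chain", "v_gene", "j_gene", "c_gene", "cdr3_nt",
                "cdr3", "umis", "reads", "productive", "high_confidence"]
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(cols)
            for r in records:
                writer.writerow([
                    r.barcode, r.contig_id, r.locus, r.v_call, r.j_call, r.c_call,
                    r.junction_nt, r.junction_aa, r.umis, r.reads,
                    "True" if r.productive else "False",
                    "True" if r.high_confidence else "False",
                ])
    elif dialect == "airr-tsv":
        cols = ["cell_id", "sequence_id", "locus", "v_call", "j_call", "c_call", "junction",
                "junction_aa", "duplicate_count", "consensus_count", "productive",
                "high_confidence", "sequence_alignment", "germline_alignment"]
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(cols)
            for r in records:
                writer.writerow([
                    r.barcode, r.contig_id, r.locus, r.v_call, r.j_call, r.c_call,
                    r.junction_nt, r.junction_aa, r.umis, r.reads,
                    "T" if r.productive else "F",
                    "T" if r.high_confidence else "F",
                    r.sequence_alignment or "", r.germline_alignment or "",
                ])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def filter_contigs(records: Sequence[ContigRecord], min_umis: int = 2) -> list[ContigRecord]:
    """Retain high-confidence, productive contigs with ``umis >= min_umis``.

    Order is preserved; the operation is idempotent.
    """
    return [r for r in records if r.high_confidence and r.productive and r.umis >= min_umis]


def qc_summary(records: Sequence[ContigRecord], min_umis: int = 2) -> dict[str, int]:
    """Count contigs removed by each QC rule (a contig may trip several)."""
    summary = {
        "input": len(records),
        "low_confidence": sum(not r.high_confidence for r in records),
        "non_productive": sum(not r.productive for r in records),
        "low_umis": sum(r.umis < min_umis for r in records),
    }
    summary["retained"] = len(filter_contigs(records, min_umis=min_umis))
    return summary


def pair_chains(records: Sequence[ContigRecord], receptor: str) -> list[CellChainSet]:
    """Group contigs by barcode and keep cells with the canonical chain pair.

    BCR cells must carry exactly one IGH and exactly one IGK-or-IGL contig;
    TCR cells exactly one TRA and one TRB.  Barcodes mixing B- and T-cell
    loci are treated as doublets and dropped with a warning.  Output order
    follows first appearance of each barcode in the input.
    """
    if receptor not in ("BCR", "TCR"):
        raise ValueError(f"receptor must be 'BCR' or 'TCR', got {receptor!r}")
    by_barcode: dict[str, list[ContigRecord]] = {}
    for rec in records:
        by_barcode.setdefault(rec.barcode, []).append(rec)

    own_loci = BCR_LOCI if receptor == "BCR" else TCR_LOCI
    cells: list[CellChainSet] = []
    for barcode, recs in by_barcode.items():
        loci = {r.locus for r in recs}
        if loci & BCR_LOCI and loci & TCR_LOCI:
            logger.warning("barcode %s carries both B and T loci; dropped as doublet", barcode)
            continue
        if not loci <= own_loci:
            continue
        if receptor == "BCR":
            heavy = [r for r in recs if r.locus == "IGH"]
            light = [r for r in recs if r.locus in ("IGK", "IGL")]
        else:
            heavy = [r for r in recs if r.locus == "TRB"]
            light = [r for r in recs if r.locus == "TRA"]
        if len(heavy) == 1 and len(light) == 1:
            cells.append(CellChainSet(barcode=barcode, receptor_type=receptor,
                                      chains=(heavy[0], light[0])))
    return cells
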