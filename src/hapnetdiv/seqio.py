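"""Sequence, population-map and report input/output.

Reads pre-aligned FASTA into an :class:`Alignment`, attaches optional
population labels from a CSV map, and serializes :class:`~hapnetdiv.metrics.MetricsReport`
objects as TSV or JSON. Population labels are carried only for reporting;
no diversity metric depends on them.
"""

from __future__ import annotations

import csv
import json
import logging
import sys
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, PopulationMapError

logger = logging.getLogger(__name__)

#: Characters accepted in aligned sequences: bases, gap, and IUPAC ambiguity.
ALLOWED_CHARS = frozenset("ACGTN-RYSWKMBDHV")
#: Characters treated as unambiguous when comparing sites.
UNAMBIGUOUS = frozenset("ACGT")

REPORT_COLUMNS = ("dataset", "n", "nH", "nHc", "Hd", "Bd", "HBd", "Nd", "HNd", "pi")
_METRIC_COLUMNS = ("Hd", "Bd", "HBd", "Nd", "HNd", "pi")

UNASSIGNED = "unassigned"


@dataclass
class Alignment:
    """An aligned set of sequences, one record per individual.

    Parameters
    ----------
    records
        Ordered ``(id, sequence)`` pairs. Sequences must share one length.
    population_of
        Optional map from individual id to population label.
    """

    records: list[tuple[str, str]]
    population_of: Optional[dict[str, str]] = field(default=None)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no records")
        ids = [rid for rid, _ in self.records]
        if any(not rid for rid in ids):
            raise AlignmentError("empty record id")
        dupes = {rid for rid in ids if ids.count(rid) > 1}
        if dupes:
            raise AlignmentError(f"duplicate record ids: {sorted(dupes)}")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            ref_len = len(self.records[0][1])
            bad = [rid for rid, seq in self.records if len(seq) != ref_len]
            raise AlignmentError(
                f"unequal sequence lengths (expected {ref_len} as in first "
                f"record): offending ids {bad}"
            )
        if len(self.records[0][1]) < 1:
            raise AlignmentError("sequences must have length >= 1")
        for rid, seq in self.records:
            extra = set(seq) - ALLOWED_CHARS
            if extra:
                raise AlignmentError(
                    f"record {rid!r} contains unsupported characters {sorted(extra)}"
                )
        if self.population_of is not None:
            missing = set(self.population_of) - set(ids)
            if missing:
                raise PopulationMapError(
                    f"population map ids not in alignment: {sorted(missing)}"
                )

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]


def _normalize(seq: str) -> str:
    # normalize dialects before haplotype hashing: uppercase, RNA U -> T
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> Alignment:
    """Read a pre-aligned FASTA file.

    Sequences are uppercased and ``U`` is mapped to ``T``. Record order is
    preserved. Raises :class:`AlignmentError` on unequal lengths, duplicate
    ids or an empty file.
    """
    records = [
        (rec.id, _normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(records=records)


def write_fasta(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment back to FASTA, preserving record order."""
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_popmap(
    path: str | Path,
    alignment: Alignment,
    id_column: str = "id",
    population_column: str = "population",
) -> Alignment:
    """Attach population labels from a CSV map to an alignment.

    The CSV must have a header containing *id_column* and *population_column*.
    Individuals absent from the map get the label ``"unassigned"`` (with a
    warning); map rows whose id is not in the alignment are an error.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or id_column not in reader.fieldnames:
            raise PopulationMapError(
                f"population map {path} lacks required column {id_column!r}"
            )
        if population_column not in reader.fieldnames:
            raise PopulationMapError(
                f"population map {path} lacks required column {population_column!r}"
            )
        for row in reader:
            rid = row[id_column].strip()
            if rid in mapping:
                raise PopulationMapError(f"duplicate id in population map: {rid!r}")
            mapping[rid] = row[population_column].strip()
    known = set(alignment.ids)
    unknown = sorted(set(mapping) - known)
    if unknown:
        raise PopulationMapError(
            f"population map ids not present in alignment: {unknown}"
        )
    unmapped = [rid for rid in alignment.ids if rid not in mapping]
    if unmapped:
        logger.warning(
            "%d individuals missing from population map, labeled %r",
            len(unmapped),
            UNASSIGNED,
        )
    full = {rid: mapping.get(rid, UNASSIGNED) for rid in alignment.ids}
    return Alignment(records=list(alignment.records), population_of=full)


def round2(value: float) -> float:
    """Round to 2 decimals, half away from zero (the convention used for the
    two-decimal report view)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _report_row(report, rounded: bool) -> list[str]:
    row: list[str] = []
    for col in REPORT_COLUMNS:
        val = getattr(report, col)
        if col == "dataset":
            row.append(f"{val}#2dp" if rounded else str(val))
        elif col in ("n", "nH", "nHc"):
            row.append(str(val))
        else:
            if val is None:
                row.append("NA")
            elif rounded:
                row.append(f"{round2(val):.2f}")
            else:
                row.append(repr(float(val)))
    return row


def write_report(report, path: str | Path | None, format: str = "tsv") -> None:
    """Write a metrics report as TSV or JSON.

    The TSV carries a fixed column order
    ``dataset,n,nH,nHc,Hd,Bd,HBd,Nd,HNd,pi`` with one full-precision row and
    one 2-decimal rounded row (dataset suffixed ``#2dp``). JSON carries full
    precision plus a ``rounded`` sub-object and the settings used.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown report format {format!r}")
    out = sys.stdout if path is None else open(path, "w")
    try:
        if format == "tsv":
            writer = csv.writer(out, delimiter="\t", lineterminator="\n")
            writer.writerow(REPORT_COLUMNS)
            writer.writerow(_report_row(report, rounded=False))
            writer.writerow(_report_row(report, rounded=True))
        else:
            payload = report.to_dict()
            payload["rounded"] = {
                col: (None if getattr(report, col) is None else round2(getattr(report, col)))
                for col in _METRIC_COLUMNS
            }
            json.dump(payload, out, indent=2, sort_keys=True)
            out.write("\n")
    finally:
        if path is not None:
            out.close()


def read_report(path: str | Path):
    """Read back a JSON report written by :func:`write_report`."""
    from .metrics import MetricsReport  # local import avoids a module cycle

    with open(path) as fh:
        payload = json.load(fh)
    payload.pop("rounded", None)
    return MetricsReport.from_dict(payload)
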