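"""Normalized gene-prediction records and the standardized protein name.

External predictor output is read from GFF3 or from a simple six-column
tabular dialect (contig, start, end, strand, frame, score).  Protein names
serialize as ``index|dataset|domain|table_id|tool1[-tool2[-tool3]]``; the
pipe and hyphen are reserved separators, so tool tokens and dataset names
must not contain them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

DOMAINS = ("Archaea", "Bacteria", "Eukaryota", "Viruses", "Unknown")

__all__ = [
    "DOMAINS",
    "GenePrediction",
    "ProteinName",
    "read_predictions",
    "write_gff3",
    "write_protein_fasta",
    "read_fasta",
]


def _check_tool_token(tool: str) -> str:
    if not tool:
        raise ValueError("tool token must be non-empty")
    if "|" in tool or "-" in tool:
        raise ValueError(
            f"tool token {tool!r} may not contain '|' or '-' "
            "(reserved name separators)")
    return tool


@dataclass(frozen=True, order=True)
class GenePrediction:
    """One tool's claim of a gene on a contig.

    Coordinates are 1-based inclusive on the forward strand with
    ``start <= end`` for both strands.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    tool: str
    partial_5p: bool = False
    partial_3p: bool = False
    frame: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"inverted coordinates {self.start} > {self.end}")
        if self.start < 1:
            raise ValueError(f"coordinates are 1-based, got {self.start}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        _check_tool_token(self.tool)

    @property
    def stop_position(self) -> int:
        """Forward-strand coordinate of the 3' terminus on the coding strand."""
        return self.end if self.strand == "+" else self.start

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinName:
    """The multi-field protein identifier, pipe-joined on serialization."""

    index: int
    dataset: str
    domain: str
    table_id: int
    tools: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("index must be a positive integer")
        if not self.dataset or "|" in self.dataset:
            raise ValueError(f"bad dataset token {self.dataset!r}")
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not self.tools:
            raise ValueError("at least one tool required")
        for t in self.tools:
            _check_tool_token(t)

    def serialize(self) -> str:
        return "|".join([str(self.index), self.dataset, self.domain,
                         str(self.table_id), "-".join(self.tools)])

    __str__ = serialize

    @classmethod
    def parse(cls, s: str) -> "ProteinName":
        parts = s.split("|")
        if len(parts) != 5:
            raise ValueError(
                f"protein name must have 5 pipe-separated fields, "
                f"got {len(parts)}: {s!r}")
        index, dataset, domain, table_id, tools = parts
        return cls(int(index), dataset, domain, int(table_id),
                   tuple(tools.split("-")))


def name_protein(p: ProteinName) -> str:
    return p.serialize()


def parse_name(s: str) -> ProteinName:
    return ProteinName.parse(s)


# ---------------------------------------------------------------------------
# readers / writers


def _gff3_records(path: Path, tool: str) -> Iterable[GenePrediction]:
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                n_bad += 1
                logger.warning("%s:%d: expected 9 columns, got %d — skipped",
                               path, lineno, len(fields))
                continue
            seqid, _src, ftype, start, end, _score, strand, phase, attrs = fields
            if ftype not in ("CDS", "gene", "ORF"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                n_bad += 1
                logger.warning("%s:%d: non-numeric coordinates — skipped",
                               path, lineno)
                continue
            partial_5p = partial_3p = False
            for kv in attrs.split(";"):
                if kv.startswith("partial="):
                    flags = kv.split("=", 1)[1]
                    partial_5p = flags[:1] == "1"
                    partial_3p = flags[1:2] == "1"
            try:
                yield GenePrediction(
                    seqid, start_i, end_i, strand, tool,
                    partial_5p=partial_5p, partial_3p=partial_3p,
                    frame=int(phase) if phase in "012" else None)
            except ValueError as exc:
                n_bad += 1
                logger.warning("%s:%d: %s — record dropped", path, lineno, exc)
    if n_bad:
        logger.warning("%s: skipped %d malformed line(s)", path, n_bad)


def _tabular_records(path: Path, tool: str) -> Iterable[GenePrediction]:
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                n_bad += 1
                logger.warning("%s:%d: expected 6 columns, got %d — skipped",
                               path, lineno, len(fields))
                continue
            contig, start, end, strand, frame, score = fields
            try:
                yield GenePrediction(
                    contig, int(start), int(end), strand, tool,
                    frame=int(frame) if frame not in (".", "") else None,
                    score=float(score) if score not in (".", "") else None)
            except ValueError as exc:
                n_bad += 1
                logger.warning("%s:%d: %s — record dropped", path, lineno, exc)
    if n_bad:
        logger.warning("%s: skipped %d malformed line(s)", path, n_bad)


def read_predictions(path: str | Path, format: str = "gff3",
                     tool: str = "tool") -> list[GenePrediction]:
    """Read one tool's predictions into normalized records.

    Malformed lines (wrong column count, inverted or non-numeric
    coordinates) are logged and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_tool_token(tool)
    if format == "gff3":
        return list(_gff3_records(path, tool))
    if format == "tabular":
        return list(_tabular_records(path, tool))
    raise ValueError(f"unknown prediction format {format!r}")


def write_gff3(records: Iterable, path: str | Path,
               source: str = "proteogut") -> None:
    """Write predictions or merged genes as GFF3 CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            tools = getattr(r, "tools", None)
            if tools is None:
                tools = (r.tool,)
            name = getattr(r, "name", None)
            attrs = f"ID={name}" if name else f"ID={r.contig_id}_{r.start}_{r.end}"
            fh.write("\t".join([
                r.contig_id, source, "CDS", str(r.start), str(r.end), ".",
                r.strand, "0", attrs + ";tools=" + ",".join(tools),
            ]) + "\n")


def write_protein_fasta(proteins: Iterable[tuple[str, str]],
                        path: str | Path, width: int = 60) -> None:
    """Write (header, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for header, seq in proteins:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (full header kept)."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        if header in seqs:
            raise ValueError(f"duplicate sequence id {header!r} in {path}")
        seqs[header] = str(rec.seq)
    return seqs
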