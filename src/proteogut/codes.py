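"""Genetic code tables, codon translation, and a six-frame ORF scanner.

Translation tables are shipped as a plain-text data file
(``data/genetic_codes.tsv``) holding, per table, the NCBI table number, the
amino acids assigned to the 64 codons in TCAG order, and the matching
start/stop annotation string.  Tables 1 (standard), 4 (TGA = Trp) and 11
(bacterial/archaeal) are provided.

The ORF scanner is a deterministic stand-in predictor: it reports, per frame
and per stop codon, the longest open reading frame (first valid start after
the previous stop).  It has no statistical gene model.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "GeneticCodeTable",
    "Contig",
    "Orf",
    "available_tables",
    "get_table",
    "load_tables",
    "translate",
    "find_orfs",
    "reverse_complement",
]

_BASES = "TCAG"
CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)

_COMPLEMENT = str.maketrans("ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
                            "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCodeTable:
    """One NCBI translation table.

    Attributes
    ----------
    table_id : NCBI translation-table number.
    codon_to_aa : mapping of all 64 codons to one-letter amino acids,
        with ``'*'`` marking stop codons.
    start_codons : codons accepted as initiators.
    stop_codons : codons terminating translation.
    """

    table_id: int
    name: str
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"table {self.table_id}: expected 64 codons, "
                f"got {len(self.codon_to_aa)}"
            )
        derived_stops = {c for c, aa in self.codon_to_aa.items() if aa == "*"}
        if derived_stops != set(self.stop_codons):
            raise ValueError(
                f"table {self.table_id}: stop codons inconsistent with "
                f"codon assignments"
            )
        if not self.start_codons:
            raise ValueError(f"table {self.table_id}: no start codons")

    @classmethod
    def from_ncbi_strings(cls, table_id: int, name: str, aas: str,
                          starts: str) -> "GeneticCodeTable":
        """Build from the 64-character NCBI amino-acid and start strings."""
        if len(aas) != 64 or len(starts) != 64:
            raise ValueError("amino-acid and start strings must be 64 chars")
        codon_to_aa = dict(zip(CODONS, aas))
        start_codons = frozenset(c for c, s in zip(CODONS, starts) if s == "M")
        stop_codons = frozenset(c for c, a in zip(CODONS, aas) if a == "*")
        return cls(table_id, name, codon_to_aa, start_codons, stop_codons)

    def translate_codon(self, codon: str) -> str:
        """Translate one codon; anything with ambiguity codes becomes 'X'."""
        codon = codon.upper().replace("U", "T")
        return self.codon_to_aa.get(codon, "X")


@dataclass
class Contig:
    """An assembled nucleotide sequence, optionally taxon-labelled."""

    contig_id: str
    sequence: str
    taxid: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Orf:
    """An open reading frame in forward-strand 1-based inclusive coordinates.

    ``start``/``end`` always satisfy ``start <= end`` regardless of strand;
    for '-' strand ORFs the start codon occupies positions
    ``end-2 .. end`` of the forward strand.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    table_id: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    def extract(self, sequence: str) -> str:
        """Coding-strand nucleotide sequence of this ORF."""
        cds = sequence[self.start - 1:self.end]
        return cds if self.strand == "+" else reverse_complement(cds)


_TABLES: dict[int, GeneticCodeTable] = {}


def load_tables(path: str | Path | None = None) -> dict[int, GeneticCodeTable]:
    """Load translation tables from a TSV data file (default: bundled)."""
    if path is None:
        ref = importlib.resources.files("proteogut.data") / "genetic_codes.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    tables: dict[int, GeneticCodeTable] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tid, name, aas, starts = line.split("\t")
        tables[int(tid)] = GeneticCodeTable.from_ncbi_strings(
            int(tid), name, aas, starts)
    return tables


def _registry() -> dict[int, GeneticCodeTable]:
    if not _TABLES:
        _TABLES.update(load_tables())
    return _TABLES


def available_tables() -> list[int]:
    return sorted(_registry())


def get_table(table_id: int) -> GeneticCodeTable:
    try:
        return _registry()[table_id]
    except KeyError:
        raise ValueError(f"unknown translation table {table_id}") from None


def translate(nt_sequence: str, table_id: int, trim_stop: bool = True) -> str:
    """Translate a nucleotide sequence under an NCBI table.

    The length must be divisible by 3.  Codons containing ambiguity codes
    translate to 'X'.  Internal stops are rendered as '*'; validity is the
    caller's decision.  With ``trim_stop`` a single terminal stop is removed.
    """
    table = get_table(table_id)
    if len(nt_sequence) % 3 != 0:
        raise ValueError(
            f"sequence length {len(nt_sequence)} not divisible by 3")
    aa = "".join(table.translate_codon(nt_sequence[i:i + 3])
                 for i in range(0, len(nt_sequence), 3))
    if trim_stop and aa.endswith("*"):
        aa = aa[:-1]
    return aa


def find_orfs(contig: Contig | str, table_id: int, min_len_nt: int = 21,
              atg_only: bool = False) -> list[Orf]:
    """Scan all six frames for maximal ORFs.

    For each stop codon in a frame, the longest compatible start (the first
    valid initiator after the previous stop) is reported, matching the
    longest-per-stop semantics of the downstream consensus merge.  The
    minimum length includes the stop codon, so ``min_len_nt=21`` means at
    least six amino acids plus a stop.  Output order is (strand, start),
    '+' before '-'.
    """
    if isinstance(contig, str):
        contig = Contig("contig", contig)
    if not contig.sequence:
        raise ValueError("empty contig sequence")
    if min_len_nt < 6:
        raise ValueError("min_len_nt must be >= 6")
    table = get_table(table_id)
    starts = frozenset({"ATG"}) if atg_only else table.start_codons
    seq = contig.sequence.upper().replace("U", "T")
    L = len(seq)
    orfs: list[Orf] = []
    for strand in "+-":
        ws = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            start_idx: int | None = None  # 0-based index into ws
            for i in range(frame, L - 2, 3):
                codon = ws[i:i + 3]
                if codon in table.stop_codons:
                    if start_idx is not None and i + 3 - start_idx >= min_len_nt:
                        if strand == "+":
                            orfs.append(Orf(contig.contig_id, start_idx + 1,
                                            i + 3, "+", table_id))
                        else:
                            orfs.append(Orf(contig.contig_id, L - i - 2,
                                            L - start_idx, "-", table_id))
                    start_idx = None
                elif start_idx is None and codon in starts:
                    start_idx = i
    orfs.sort(key=lambda o: (o.strand, o.start, o.end))
    return orfs
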