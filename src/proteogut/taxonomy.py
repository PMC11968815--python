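"""Route contigs to (domain, genetic code) groups from taxon assignments.

No classifier runs here: assignments are consumed from Kraken-style output
or a two-column contig/taxid table, and resolved against a flat rule table
(taxid, parent, domain, translation table).  Unclassified contigs take the
bacteria-default route with table 11 but keep the distinct "Unknown" domain
label; host-assigned contigs are excluded from prediction entirely.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

UNKNOWN_ROUTE = ("Unknown", 11)

__all__ = [
    "TaxonAssignment",
    "LineageRule",
    "RuleTable",
    "RoutingResult",
    "load_rules",
    "read_kraken",
    "read_taxid_table",
    "read_assignments",
    "route_contigs",
]


@dataclass(frozen=True)
class TaxonAssignment:
    """A contig's taxon call; ``taxid=None`` means unclassified."""

    contig_id: str
    taxid: int | None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.taxid is not None and self.taxid < 0:
            raise ValueError(f"negative taxid {self.taxid}")


@dataclass(frozen=True)
class LineageRule:
    taxid: int
    parent: int
    domain: str
    table_id: int | None  # None for Host rules

    def __post_init__(self) -> None:
        if self.domain == "Host" and self.table_id is not None:
            raise ValueError("Host rules carry no translation table")


class RuleTable:
    """Flat taxid -> (domain, table) rules with parent links for fallback."""

    def __init__(self, rules: Iterable[LineageRule]):
        self.rules: dict[int, LineageRule] = {}
        for r in rules:
            if r.taxid in self.rules:
                raise ValueError(f"duplicate rule for taxid {r.taxid}")
            self.rules[r.taxid] = r

    def resolve(self, taxid: int | None) -> tuple[str, int] | None:
        """Nearest rule on the parent path; None for unclassified/unknown.

        Host resolution returns ``("Host", -1)`` as a sentinel.
        """
        seen: set[int] = set()
        while taxid is not None and taxid > 0 and taxid not in seen:
            seen.add(taxid)
            rule = self.rules.get(taxid)
            if rule is None:
                return None
            if rule.domain == "Host":
                return ("Host", -1)
            if rule.table_id is not None:
                return (rule.domain, rule.table_id)
            # link-only node (no table): defer to the nearest ancestor rule
            taxid = rule.parent if rule.parent > 0 else None
        return None


def load_rules(path: str | Path | None = None) -> RuleTable:
    """Load a rule table TSV (default: bundled sensible defaults)."""
    if path is None:
        text = (importlib.resources.files("proteogut.data")
                / "lineage_rules.tsv").read_text()
    else:
        text = Path(path).read_text()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        taxid, parent, domain, table = line.split("\t")
        rules.append(LineageRule(
            int(taxid), int(parent), domain,
            None if table in ("-", "") else int(table)))
    return RuleTable(rules)


def read_kraken(path: str | Path) -> list[TaxonAssignment]:
    """Parse Kraken-2 standard output (C/U, id, taxid, length, LCA string)."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            status, contig_id, taxid = fields[0], fields[1], fields[2]
            if status == "U" or taxid in ("0", "unclassified"):
                out.append(TaxonAssignment(contig_id, None))
            else:
                out.append(TaxonAssignment(contig_id, int(taxid)))
    return out


def read_taxid_table(path: str | Path) -> list[TaxonAssignment]:
    """Parse a two-column contig<TAB>taxid table ('0' or '-' = unclassified)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            contig_id, taxid = line.split("\t")[:2]
            out.append(TaxonAssignment(
                contig_id,
                None if taxid in ("0", "-", "unclassified") else int(taxid)))
    return out


def read_assignments(path: str | Path) -> list[TaxonAssignment]:
    """Auto-detect Kraken vs. plain two-column assignment format."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line.split("\t")[0]
                if first in ("C", "U"):
                    return read_kraken(path)
                return read_taxid_table(path)
    return []


@dataclass
class RoutingResult:
    routes: dict[str, tuple[str, int]]
    host_excluded: list[str]

    @property
    def n_host_excluded(self) -> int:
        return len(self.host_excluded)


def route_contigs(assignments: Sequence[TaxonAssignment],
                  rules: RuleTable | None = None,
                  contig_ids: Iterable[str] | None = None) -> RoutingResult:
    """Map every contig to its (domain, table_id) prediction route.

    Contigs named in ``contig_ids`` but absent from the assignments are
    treated as unclassified.  Duplicate assignments: first wins, with a
    warning.  Routing is a pure function of (taxid, rules).
    """
    if rules is None:
        rules = load_rules()
    routes: dict[str, tuple[str, int]] = {}
    host: list[str] = []
    seen: set[str] = set()
    for a in assignments:
        if a.contig_id in seen:
            logger.warning("duplicate assignment for %s ignored (first wins)",
                           a.contig_id)
            continue
        seen.add(a.contig_id)
        resolved = rules.resolve(a.taxid)
        if resolved is None:
            routes[a.contig_id] = UNKNOWN_ROUTE
        elif resolved[0] == "Host":
            host.append(a.contig_id)
        else:
            routes[a.contig_id] = resolved
    if contig_ids is not None:
        for cid in contig_ids:
            if cid not in seen:
                routes[cid] = UNKNOWN_ROUTE
    if host:
        logger.info("excluded %d host contig(s) from prediction", len(host))
    return RoutingResult(routes, host)
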