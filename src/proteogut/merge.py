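"""Consensus merging of multi-tool gene predictions.

Predictions are grouped by strand and 3'-terminus (the stop end on the
coding strand).  Within a group the longest span wins; groups with distinct
stops are all kept.  Kept genes then pass the edge-partial filter (start
codon within the first or last three bases of the contig), the minimum
length filter (default 21 nt: six amino acids plus a stop codon), and
translation under the contig's routed genetic code — survivors whose
translation contains an internal stop are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .codes import Contig, find_orfs, get_table, reverse_complement, translate
from .predictions import (GenePrediction, ProteinName, write_gff3,
                          write_protein_fasta)
from .taxonomy import RoutingResult, RuleTable, TaxonAssignment, route_contigs

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN_NT = 21
DEFAULT_MIN_PROTEINS = 1000

__all__ = [
    "MergedGene",
    "MergeStats",
    "PipelineResult",
    "merge_coordinates",
    "merge_contig",
    "merge_predictions",
    "run_pipeline",
]


@dataclass(frozen=True)
class MergedGene:
    """A deduplicated, filtered, translated consensus gene."""

    contig_id: str
    start: int
    end: int
    strand: str
    tools: tuple[str, ...]
    table_id: int
    cds: str
    protein: str
    name: str | None = None

    @property
    def stop_position(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    def with_name(self, name: ProteinName) -> "MergedGene":
        return MergedGene(self.contig_id, self.start, self.end, self.strand,
                          self.tools, self.table_id, self.cds, self.protein,
                          name.serialize())


@dataclass
class MergeStats:
    """Per-filter accounting; conserves counts on the stop-group level."""

    n_input: int = 0
    n_out_of_bounds: int = 0
    n_groups: int = 0
    n_edge_filtered: int = 0
    n_length_filtered: int = 0
    n_bad_frame: int = 0
    n_internal_stop_filtered: int = 0
    n_output: int = 0

    def __add__(self, other: "MergeStats") -> "MergeStats":
        return MergeStats(*(getattr(self, f) + getattr(other, f)
                            for f in self.__dataclass_fields__))


def merge_coordinates(
        preds: Sequence[GenePrediction]) -> list[tuple[GenePrediction, tuple[str, ...]]]:
    """Coordinate-level consensus: one winner per (strand, stop) group.

    Returns (winner, credited tools) pairs in deterministic (strand, start)
    order.  Credit goes only to tools whose prediction has coordinates
    identical to the winner's; tools of shorter same-stop predictions are
    not credited.
    """
    groups: dict[tuple[str, str, int], list[GenePrediction]] = defaultdict(list)
    for p in preds:
        groups[(p.contig_id, p.strand, p.stop_position)].append(p)
    out = []
    for key in sorted(groups):
        members = groups[key]
        winner = max(members, key=lambda p: p.length_nt)
        tools = tuple(sorted({p.tool for p in members
                              if (p.start, p.end) == (winner.start, winner.end)}))
        out.append((winner, tools))
    out.sort(key=lambda pair: (pair[0].strand, pair[0].start, pair[0].end))
    return out


def merge_contig(contig: Contig, preds: Sequence[GenePrediction],
                 table_id: int, min_len_nt: int = DEFAULT_MIN_LEN_NT,
                 keep_internal_stop: bool = False,
                 ) -> tuple[list[MergedGene], MergeStats]:
    """Merge one contig's predictions and return genes plus filter counts."""
    get_table(table_id)  # validate early
    stats = MergeStats(n_input=len(preds))
    L = len(contig.sequence)
    in_bounds = []
    for p in preds:
        if p.contig_id != contig.contig_id or p.end > L:
            stats.n_out_of_bounds += 1
            logger.warning("prediction %s:%d-%d outside contig %s — dropped",
                           p.contig_id, p.start, p.end, contig.contig_id)
        else:
            in_bounds.append(p)

    winners = merge_coordinates(in_bounds)
    stats.n_groups = len(winners)

    genes: list[MergedGene] = []
    for winner, tools in winners:
        # edge-partial removal: start codon within 3 bases of either edge
        if winner.strand == "+" and winner.start <= 3:
            stats.n_edge_filtered += 1
            continue
        if winner.strand == "-" and winner.end >= L - 2:
            stats.n_edge_filtered += 1
            continue
        if winner.length_nt < min_len_nt:
            stats.n_length_filtered += 1
            continue
        cds = contig.sequence[winner.start - 1:winner.end]
        if winner.strand == "-":
            cds = reverse_complement(cds)
        if len(cds) % 3 != 0:
            stats.n_bad_frame += 1
            logger.warning("gene %s:%d-%d length not divisible by 3 — dropped",
                           winner.contig_id, winner.start, winner.end)
            continue
        protein = translate(cds, table_id, trim_stop=True)
        if "*" in protein and not keep_internal_stop:
            stats.n_internal_stop_filtered += 1
            logger.warning("gene %s:%d-%d has internal stop(s) under table "
                           "%d — dropped", winner.contig_id, winner.start,
                           winner.end, table_id)
            continue
        genes.append(MergedGene(contig.contig_id, winner.start, winner.end,
                                winner.strand, tools, table_id, cds, protein))
    genes.sort(key=lambda g: (g.strand, g.start, g.end))
    stats.n_output = len(genes)
    return genes, stats


def merge_predictions(contig: Contig, preds: Sequence[GenePrediction],
                      table_id: int, **kwargs) -> list[MergedGene]:
    """Like :func:`merge_contig`, returning only the gene list."""
    return merge_contig(contig, preds, table_id, **kwargs)[0]


@dataclass
class PipelineResult:
    dataset: str
    genes: list[MergedGene]
    stats: MergeStats
    domain_counts: dict[str, int]
    n_host_excluded: int
    rejected: bool

    @property
    def n_proteins(self) -> int:
        return len(self.genes)


def run_pipeline(contigs: Sequence[Contig],
                 assignments: Sequence[TaxonAssignment],
                 predictions: Mapping[str, Sequence[GenePrediction]] | None = None,
                 *,
                 dataset: str = "dataset",
                 rules: RuleTable | None = None,
                 use_internal_caller: bool = False,
                 min_len_nt: int = DEFAULT_MIN_LEN_NT,
                 min_proteins: int | None = DEFAULT_MIN_PROTEINS,
                 keep_internal_stop: bool = False,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Route contigs, merge per-tool predictions, and emit named proteins.

    ``predictions`` maps tool token to that tool's records across all
    contigs; with ``use_internal_caller`` the built-in ORF scanner is run
    (additionally) as tool "proteogut".  Proteins are numbered sequentially
    in output order and named ``index|dataset|domain|table|tools``.  With
    ``min_proteins`` set, datasets yielding fewer proteins are flagged
    rejected (the flag is reported; outputs are still written).
    """
    if not contigs:
        raise ValueError("empty dataset: no contigs")
    routing = route_contigs(assignments, rules,
                            contig_ids=[c.contig_id for c in contigs])
    by_contig: dict[str, list[GenePrediction]] = defaultdict(list)
    known = {c.contig_id for c in contigs}
    if predictions:
        for tool, recs in predictions.items():
            for p in recs:
                if p.contig_id not in known:
                    logger.warning("prediction on unknown contig %s — dropped",
                                   p.contig_id)
                    continue
                by_contig[p.contig_id].append(p)

    genes: list[MergedGene] = []
    total_stats = MergeStats()
    domain_counts: dict[str, int] = defaultdict(int)
    index = 0
    for contig in contigs:
        route = routing.routes.get(contig.contig_id)
        if route is None:  # host contig
            continue
        domain, table_id = route
        preds = list(by_contig.get(contig.contig_id, []))
        if use_internal_caller:
            preds.extend(
                GenePrediction(o.contig_id, o.start, o.end, o.strand,
                               "proteogut")
                for o in find_orfs(contig, table_id, min_len_nt=min_len_nt))
        merged, stats = merge_contig(contig, preds, table_id,
                                     min_len_nt=min_len_nt,
                                     keep_internal_stop=keep_internal_stop)
        total_stats = total_stats + stats
        for g in merged:
            index += 1
            genes.append(g.with_name(
                ProteinName(index, dataset, domain, table_id, g.tools)))
            domain_counts[domain] += 1

    rejected = min_proteins is not None and len(genes) < min_proteins
    if rejected:
        logger.warning("dataset %s rejected: %d proteins < threshold %d",
                       dataset, len(genes), min_proteins)
    result = PipelineResult(dataset, genes, total_stats, dict(domain_counts),
                            routing.n_host_excluded, rejected)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_protein_fasta(((g.name, g.protein) for g in genes),
                            out_dir / f"{dataset}.proteins.faa")
        write_gff3(genes, out_dir / f"{dataset}.genes.gff3")
        _write_summary(result, out_dir / f"{dataset}.summary.tsv")
    return result


def _write_summary(result: PipelineResult, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"dataset\t{result.dataset}\n")
        fh.write(f"n_proteins\t{result.n_proteins}\n")
        fh.write(f"rejected\t{str(result.rejected).lower()}\n")
        fh.write(f"n_host_excluded\t{result.n_host_excluded}\n")
        for domain in sorted(result.domain_counts):
            fh.write(f"n_proteins_{domain}\t{result.domain_counts[domain]}\n")
        for f in result.stats.__dataclass_fields__:
            fh.write(f"{f}\t{getattr(result.stats, f)}\n")
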