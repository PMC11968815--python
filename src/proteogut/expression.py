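"""Metatranscriptomic quantification against a protein catalogue.

Read-to-protein alignments are consumed from BLAST-style tabular files with
best-hit (one target per read) counting.  Per sample: aligned read
fraction; per protein cluster: RPKM and expression prevalence across
samples ("expressed" = at least one mapped read to any member, configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

HIGH_PREVALENCE_THRESHOLD = 0.9

__all__ = [
    "AlignmentCounts",
    "ExpressionSummary",
    "read_alignment_counts",
    "aligned_fraction",
    "rpkm",
    "expression_prevalence",
]


@dataclass
class AlignmentCounts:
    """Per-sample read-mapping tallies (best-hit: one target per read)."""

    sample_id: str
    total_reads: int
    aligned_reads: int
    per_target_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aligned_reads > self.total_reads:
            raise ValueError("aligned_reads exceeds total_reads")
        if sum(self.per_target_reads.values()) > self.aligned_reads:
            raise ValueError("per-target reads exceed aligned total")


@dataclass
class ExpressionSummary:
    cluster_id: str
    n_samples_expressed: int
    n_samples: int
    rpkm_per_sample: dict[str, float]

    @property
    def prevalence(self) -> float:
        return self.n_samples_expressed / self.n_samples

    @property
    def high_prevalence(self) -> bool:
        return self.prevalence > HIGH_PREVALENCE_THRESHOLD


def read_alignment_counts(path: str | Path, sample_id: str,
                          total_reads: int) -> AlignmentCounts:
    """Tally a BLAST/DIAMOND outfmt-6 file, keeping one hit per read.

    The first line per read id wins, matching '-k 1 --max-hsps 1' output
    where the best hit is printed first.
    """
    per_target: dict[str, int] = {}
    seen_reads: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            read_id, target = fields[0], fields[1]
            if read_id in seen_reads:
                continue
            seen_reads.add(read_id)
            per_target[target] = per_target.get(target, 0) + 1
    return AlignmentCounts(sample_id, total_reads, len(seen_reads),
                           per_target)


def aligned_fraction(counts: AlignmentCounts) -> float:
    """Percentage of the sample's reads that aligned: (aligned/total) x 100."""
    if counts.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return 100.0 * counts.aligned_reads / counts.total_reads


def rpkm(aligned_to_gene: int, gene_length_nt: int, total_reads: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_nt <= 0:
        raise ValueError("gene length must be positive")
    if total_reads <= 0:
        raise ValueError("library size must be positive")
    return aligned_to_gene / ((gene_length_nt / 1000.0)
                              * (total_reads / 1_000_000.0))


def expression_prevalence(per_sample_counts: Sequence[AlignmentCounts],
                          cluster_members: Mapping[str, Sequence[str]],
                          rep_length_nt: Mapping[str, int],
                          min_reads: int = 1) -> list[ExpressionSummary]:
    """Expression summary per cluster across metatranscriptomic samples.

    A cluster is expressed in a sample when at least ``min_reads`` reads map
    to any of its members; RPKM sums member reads and uses the
    representative's length.  Targets not covered by the membership mapping
    are warned about once.
    """
    member_to_cluster: dict[str, str] = {}
    for cid, members in cluster_members.items():
        for m in members:
            member_to_cluster[m] = cid
    unmapped: set[str] = set()
    n_samples = len(per_sample_counts)
    summaries = []
    for cid in sorted(cluster_members):
        members = set(cluster_members[cid])
        n_expressed = 0
        rpkms: dict[str, float] = {}
        for counts in per_sample_counts:
            reads = sum(v for t, v in counts.per_target_reads.items()
                        if t in members)
            if reads >= min_reads:
                n_expressed += 1
            rpkms[counts.sample_id] = rpkm(reads, rep_length_nt[cid],
                                           counts.total_reads)
        summaries.append(ExpressionSummary(cid, n_expressed, n_samples, rpkms))
    for counts in per_sample_counts:
        unmapped |= {t for t in counts.per_target_reads
                     if t not in member_to_cluster}
    if unmapped:
        logger.warning("%d aligned target(s) not in any cluster: %s",
                       len(unmapped), sorted(unmapped)[:5])
    return summaries
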