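"""Pairwise identity/coverage scoring shared by clustering and search.

Definitions (fixed and documented, since upstream tools each choose their
own): sequences are compared by Smith-Waterman local alignment (match +1,
mismatch -1, gap -1); identity = identical columns / alignment columns;
coverage of a sequence = aligned span on that sequence / its length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

__all__ = ["PairwiseScore", "score_pair", "shares_kmer", "kmer_set"]


@dataclass(frozen=True)
class PairwiseScore:
    identity: float          # matches / alignment columns
    coverage_a: float        # aligned span on a / len(a)
    coverage_b: float        # aligned span on b / len(b)
    coverage_shorter: float  # coverage of whichever sequence is shorter


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def score_pair(a: str, b: str) -> PairwiseScore:
    """Identity and per-sequence coverage of the best local alignment."""
    if not a or not b:
        return PairwiseScore(0.0, 0.0, 0.0, 0.0)
    alignments = _ALIGNER.align(a, b)
    try:
        best = alignments[0]
    except IndexError:
        return PairwiseScore(0.0, 0.0, 0.0, 0.0)
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return PairwiseScore(0.0, 0.0, 0.0, 0.0)
    a_blocks, b_blocks = best.aligned
    span_a = a_blocks[-1][1] - a_blocks[0][0]
    span_b = b_blocks[-1][1] - b_blocks[0][0]
    cov_a = span_a / len(a)
    cov_b = span_b / len(b)
    cov_short = (span_a / len(a)) if len(a) <= len(b) else (span_b / len(b))
    return PairwiseScore(counts.identities / columns, cov_a, cov_b, cov_short)


def kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        return frozenset()
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def shares_kmer(kmers_a: frozenset[str], kmers_b: frozenset[str]) -> bool:
    return not kmers_a.isdisjoint(kmers_b)
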