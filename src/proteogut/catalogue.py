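"""Non-redundant protein catalogue construction and catalogue analyses.

Greedy longest-first clustering at identity/coverage thresholds (defaults
0.9 identity, 0.8 coverage of the shorter sequence), with an exact-k-mer
prefilter that is provably lossless at identity >= 0.9 and therefore must
agree with brute-force all-pairs verification.  Also: directed catalogue
overlap by co-clustering, and permutation rarefaction curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import kmer_set, score_pair

SPC_MAX_REP_LEN = 50  # small-protein cluster: representative <= 50 aa
PREFILTER_K = 4
# below this length a lossless shared-k-mer guarantee no longer holds
PREFILTER_MIN_LEN = 10

__all__ = [
    "ProteinCluster",
    "cluster",
    "brute_force_cluster",
    "overlap",
    "rarefaction",
    "write_clusters_tsv",
]


@dataclass
class ProteinCluster:
    """A representative plus its members at the clustering thresholds."""

    rep_id: str
    member_ids: list[str]
    rep_len: int

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1

    @property
    def is_spc(self) -> bool:
        return self.rep_len <= SPC_MAX_REP_LEN

    def __post_init__(self) -> None:
        if self.rep_id not in self.member_ids:
            raise ValueError("representative must be a member of its cluster")


def _ordered_items(proteins: Mapping[str, str]) -> list[tuple[str, str]]:
    if not proteins:
        raise ValueError("empty protein input")
    # longest first; ties broken by lexicographically smallest id
    return sorted(proteins.items(), key=lambda kv: (-len(kv[1]), kv[0]))


def _passes(seq: str, rep_seq: str, id_threshold: float,
            cov_threshold: float) -> bool:
    s = score_pair(seq, rep_seq)
    return s.identity >= id_threshold and s.coverage_shorter >= cov_threshold


def cluster(proteins: Mapping[str, str], id_threshold: float = 0.9,
            cov_threshold: float = 0.8,
            use_prefilter: bool | None = None) -> list[ProteinCluster]:
    """Greedy longest-first clustering.

    Each sequence joins the first (creation-order) existing cluster whose
    representative it matches at both thresholds, otherwise founds a new
    cluster; representatives are therefore always the longest members.
    The k-mer prefilter is only applied when ``id_threshold >= 0.9`` (where
    a shared 4-mer is guaranteed for any passing pair of length >= 10);
    at lower thresholds all representatives are alignment-verified.
    """
    if not (0 < id_threshold <= 1 and 0 < cov_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if use_prefilter is None:
        use_prefilter = id_threshold >= 0.9
    items = _ordered_items(proteins)
    clusters: list[ProteinCluster] = []
    rep_seqs: list[str] = []
    rep_kmers: list[frozenset[str]] = []
    for pid, seq in items:
        placed = False
        qkmers = kmer_set(seq, PREFILTER_K) if use_prefilter else None
        for ci, rep_seq in enumerate(rep_seqs):
            if (use_prefilter
                    and len(seq) >= PREFILTER_MIN_LEN
                    and len(rep_seq) >= PREFILTER_MIN_LEN
                    and qkmers.isdisjoint(rep_kmers[ci])):
                continue
            if _passes(seq, rep_seq, id_threshold, cov_threshold):
                clusters[ci].member_ids.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(ProteinCluster(pid, [pid], len(seq)))
            rep_seqs.append(seq)
            rep_kmers.append(kmer_set(seq, PREFILTER_K) if use_prefilter
                             else frozenset())
    return clusters


def brute_force_cluster(proteins: Mapping[str, str], id_threshold: float = 0.9,
                        cov_threshold: float = 0.8) -> list[ProteinCluster]:
    """Reference implementation: same greedy order, every candidate pair
    verified by full alignment (no prefilter)."""
    return cluster(proteins, id_threshold, cov_threshold, use_prefilter=False)


def overlap(catalogue_a: Mapping[str, str], catalogue_b: Mapping[str, str],
            id_threshold: float = 0.9, cov_threshold: float = 0.8,
            ) -> tuple[float, float]:
    """Directed co-clustering coverage between two catalogues.

    Proteins of the two inputs are pooled (ids namespaced), reclustered at
    the same thresholds, and a protein of A counts as covered by B if its
    cluster contains at least one B protein (and vice versa).  Returns
    (fraction of A covered by B, fraction of B covered by A).
    """
    pooled = {f"A\x00{k}": v for k, v in catalogue_a.items()}
    pooled.update({f"B\x00{k}": v for k, v in catalogue_b.items()})
    clusters_ = cluster(pooled, id_threshold, cov_threshold)
    a_covered = b_covered = 0
    for cl in clusters_:
        has_a = any(m.startswith("A\x00") for m in cl.member_ids)
        has_b = any(m.startswith("B\x00") for m in cl.member_ids)
        if has_a and has_b:
            a_covered += sum(m.startswith("A\x00") for m in cl.member_ids)
            b_covered += sum(m.startswith("B\x00") for m in cl.member_ids)
    return a_covered / len(catalogue_a), b_covered / len(catalogue_b)


def rarefaction(sample_to_clusters: Mapping[str, Iterable[str]],
                n_permutations: int = 100,
                quantiles: Sequence[float] = (0.5,),
                seed: int | np.random.Generator = 0,
                exhaustive: bool = False,
                ) -> tuple[np.ndarray, dict[float, int]]:
    """Permutation accumulation curve of distinct clusters per sample depth.

    Returns the mean cumulative distinct-cluster count at each depth
    (1..n_samples) over ``n_permutations`` random sample orderings (or over
    every ordering with ``exhaustive``, feasible for small sample counts),
    and for each requested quantile q the smallest depth whose mean count
    reaches q * total distinct clusters.
    """
    if not sample_to_clusters:
        raise ValueError("need at least one sample")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    samples = sorted(sample_to_clusters)
    sets = [frozenset(sample_to_clusters[s]) for s in samples]
    n = len(samples)
    total = len(frozenset().union(*sets))
    if exhaustive:
        from itertools import permutations
        orders = list(permutations(range(n)))
    else:
        orders = [rng.permutation(n) for _ in range(n_permutations)]
    curve = np.zeros(n)
    for order in orders:
        seen: set[str] = set()
        for depth, idx in enumerate(order):
            seen |= sets[idx]
            curve[depth] += len(seen)
    curve /= len(orders)
    depths = {}
    for q in quantiles:
        target = q * total
        reached = np.nonzero(curve >= target - 1e-9)[0]
        depths[q] = int(reached[0]) + 1 if reached.size else n
    return curve, depths


def write_clusters_tsv(clusters: Sequence[ProteinCluster], path) -> None:
    """MMseqs2-style two-column membership table (rep_id, member_id)."""
    with open(path, "w") as fh:
        for cl in clusters:
            for m in cl.member_ids:
                fh.write(f"{cl.rep_id}\t{m}\n")
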