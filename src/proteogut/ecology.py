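"""Protein-ecology statistics across gut samples.

Queries are matched to a predicted-protein corpus at identity/coverage
thresholds (default 0.9/0.9/0.9), presence is summarised per metadata group
with a two-sided Fisher exact test (probability-mass rule, computed in
log-space) and Benjamini-Hochberg correction applied within each metadata
variable, multi-protein queries are intersected, and the function-positive
fraction is the cumulative relative abundance of positive genomes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import kmer_set, score_pair
from .predictions import ProteinName

logger = logging.getLogger(__name__)

__all__ = [
    "QueryHit",
    "PrevalenceResult",
    "TaxonomicRange",
    "search",
    "read_hits_table",
    "fisher_exact",
    "bh_adjust",
    "prevalence_analysis",
    "presence_by_sample",
    "multi_protein_presence",
    "function_positive_fraction",
    "taxonomic_range",
]

DEFAULT_AGE_BINS = (0, 18, 30, 40, 50, 60, 70, 200)
DEFAULT_BMI_BINS = (0, 18.5, 25, 30, 100)
DISEASE_FLAGS = ("CD", "UC", "CRC", "CDI", "T2D", "RA", "FL")
CATEGORICAL_VARIABLES = ("age", "sex", "bmi", "country", "westernised",
                         "smoker", "antibiotics")
_TRUE = {"yes", "y", "true", "1", "t"}
_FALSE = {"no", "n", "false", "0", "f"}


@dataclass(frozen=True)
class QueryHit:
    """A thresholded match of a query protein to a corpus protein."""

    query_id: str
    subject_id: str
    identity: float
    query_cov: float
    subject_cov: float

    @property
    def sample_or_genome(self) -> str:
        """Dataset token parsed from the standardized subject name."""
        try:
            return ProteinName.parse(self.subject_id).dataset
        except ValueError:
            return self.subject_id


@dataclass
class PrevalenceResult:
    variable: str
    group_label: str
    n_present: int
    n_total: int
    p_value: float
    q_value: float | None = None
    comparison: str = "rest"

    @property
    def prevalence(self) -> float:
        return self.n_present / self.n_total if self.n_total else float("nan")


# ---------------------------------------------------------------------------
# sequence search


def search(queries: Mapping[str, str], corpus: Mapping[str, str],
           id_min: float = 0.9, qcov_min: float = 0.9,
           scov_min: float = 0.9, prefilter_k: int = 4) -> list[QueryHit]:
    """All-vs-corpus protein search by local alignment.

    A hit requires identity, query coverage, and subject coverage to all
    reach their thresholds.  An exact shared-k-mer prefilter skips hopeless
    subjects when the identity threshold is high enough for it to be safe.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if not (0 < id_min <= 1 and 0 < qcov_min <= 1 and 0 < scov_min <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    use_prefilter = id_min >= 0.9
    corpus_kmers = {sid: kmer_set(s, prefilter_k) for sid, s in corpus.items()} \
        if use_prefilter else {}
    hits: list[QueryHit] = []
    for qid in sorted(queries):
        qseq = queries[qid]
        qk = kmer_set(qseq, prefilter_k) if use_prefilter else None
        for sid in sorted(corpus):
            sseq = corpus[sid]
            if (use_prefilter and len(qseq) >= 10 and len(sseq) >= 10
                    and qk.isdisjoint(corpus_kmers[sid])):
                continue
            s = score_pair(qseq, sseq)
            if (s.identity >= id_min and s.coverage_a >= qcov_min
                    and s.coverage_b >= scov_min):
                hits.append(QueryHit(qid, sid, s.identity,
                                     s.coverage_a, s.coverage_b))
    return hits


def read_hits_table(path: str | Path, query_lengths: Mapping[str, int],
                    subject_lengths: Mapping[str, int],
                    id_min: float = 0.9, qcov_min: float = 0.9,
                    scov_min: float = 0.9) -> list[QueryHit]:
    """Filter a precomputed BLAST/DIAMOND outfmt-6 table into QueryHits.

    Coverage is computed from the aligned query/subject ranges and the
    supplied sequence lengths; percent identity is rescaled to a fraction.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qid, sid = f[0], f[1]
            pident = float(f[2]) / 100.0
            qstart, qend, sstart, send = (int(f[6]), int(f[7]),
                                          int(f[8]), int(f[9]))
            if qid not in query_lengths or sid not in subject_lengths:
                logger.warning("hit with unknown sequence %s/%s skipped",
                               qid, sid)
                continue
            qcov = (abs(qend - qstart) + 1) / query_lengths[qid]
            scov = (abs(send - sstart) + 1) / subject_lengths[sid]
            if pident >= id_min and qcov >= qcov_min and scov >= scov_min:
                hits.append(QueryHit(qid, sid, pident, qcov, scov))
    return hits


def presence_by_sample(hits: Iterable[QueryHit],
                       samples: Iterable[str]) -> dict[str, bool]:
    """Presence/absence per sample: one valid hit suffices."""
    positive = {h.sample_or_genome for h in hits}
    return {s: s in positive for s in samples}


# ---------------------------------------------------------------------------
# statistics


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    # log P(X = a) for the 2x2 table with fixed margins
    n = r1 + r2
    return (math.lgamma(r1 + 1) - math.lgamma(a + 1) - math.lgamma(r1 - a + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - a + 1)
            - math.lgamma(r2 - c1 + a + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1)
               - math.lgamma(n - c1 + 1)))


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact test on a 2x2 table.

    Probability-mass rule: p is the sum over all tables with the observed
    margins whose hypergeometric probability does not exceed that of the
    observed table (relative tolerance 1e-7), evaluated in log-space.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 + r2 == 0:
        raise ValueError("empty table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == r1 + r2:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    cutoff = log_obs + math.log(1 + 1e-7)
    logs = [_log_hypergeom_pmf(x, r1, r2, c1) for x in range(lo, hi + 1)]
    selected = [lp for lp in logs if lp <= cutoff]
    m = max(selected)
    p = math.exp(m) * sum(math.exp(lp - m) for lp in selected)
    return min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# prevalence across metadata groups


def _as_bool(value) -> bool | None:
    if pd.isna(value):
        return None
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    return None


def _group_series(meta: pd.DataFrame, variable: str,
                  age_bins: Sequence[float],
                  bmi_bins: Sequence[float]) -> pd.Series:
    if variable not in meta.columns:
        return pd.Series(dtype=object)
    col = meta[variable]
    if variable == "age":
        numeric = pd.to_numeric(col, errors="coerce")
        return pd.cut(numeric, bins=list(age_bins)).astype(str).where(
            numeric.notna())
    if variable == "bmi":
        numeric = pd.to_numeric(col, errors="coerce")
        return pd.cut(numeric, bins=list(bmi_bins)).astype(str).where(
            numeric.notna())
    return col.where(col.notna()).astype(object)


def prevalence_analysis(presence: Mapping[str, bool], metadata: pd.DataFrame,
                        mode: str = "categorical",
                        variables: Sequence[str] | None = None,
                        disease_flags: Sequence[str] | None = None,
                        age_bins: Sequence[float] = DEFAULT_AGE_BINS,
                        bmi_bins: Sequence[float] = DEFAULT_BMI_BINS,
                        sample_column: str = "sample_id",
                        ) -> list[PrevalenceResult]:
    """Prevalence of a (set of) queried protein(s) per metadata group.

    ``mode="categorical"``: each group of each variable is compared against
    the remaining samples of that variable.  ``mode="disease-vs-healthy"``:
    each disease flag's positives are compared against healthy controls
    (samples negative for every disease flag).  Samples with missing
    metadata are excluded per variable; BH correction is applied within
    each variable family.
    """
    meta = metadata.set_index(sample_column) if sample_column in metadata.columns \
        else metadata
    meta = meta.loc[[s for s in meta.index if s in presence]]
    pres = pd.Series({s: bool(presence[s]) for s in meta.index})

    results: list[PrevalenceResult] = []
    if mode == "categorical":
        variables = variables or [v for v in CATEGORICAL_VARIABLES
                                  if v in meta.columns]
        for variable in variables:
            groups = _group_series(meta, variable, age_bins, bmi_bins)
            valid = groups.notna()
            fam: list[PrevalenceResult] = []
            for label in sorted(groups[valid].unique()):
                in_g = valid & (groups == label)
                out_g = valid & (groups != label)
                n_total = int(in_g.sum())
                if n_total == 0:
                    continue
                a = int(pres[in_g].sum())
                c = int(pres[out_g].sum())
                p = fisher_exact([[a, n_total - a],
                                  [c, int(out_g.sum()) - c]])
                fam.append(PrevalenceResult(variable, str(label), a, n_total,
                                            p, comparison="rest"))
            _attach_q(fam)
            results.extend(fam)
    elif mode == "disease-vs-healthy":
        flags = [f for f in (disease_flags or DISEASE_FLAGS)
                 if f in meta.columns]
        flag_bools = {f: meta[f].map(_as_bool) for f in flags}
        healthy = pd.Series(True, index=meta.index)
        for f in flags:
            healthy &= flag_bools[f].fillna(False).astype(bool).eq(False)
        n_healthy = int(healthy.sum())
        if n_healthy == 0:
            logger.warning("no healthy controls — disease comparison skipped")
            return []
        h_present = int(pres[healthy].sum())
        fam = []
        for f in flags:
            is_case = flag_bools[f].apply(lambda v: v is True)
            n_cases = int(is_case.sum())
            if n_cases == 0:
                logger.warning("disease %s: no cases — skipped", f)
                continue
            a = int(pres[is_case].sum())
            p = fisher_exact([[a, n_cases - a],
                              [h_present, n_healthy - h_present]])
            fam.append(PrevalenceResult(f, f, a, n_cases, p,
                                        comparison="healthy"))
        _attach_q(fam)
        if fam:
            fam.append(PrevalenceResult("healthy", "healthy", h_present,
                                        n_healthy, 1.0, 1.0, "self"))
        results.extend(fam)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return results


def _attach_q(family: list[PrevalenceResult]) -> None:
    if family:
        qs = bh_adjust([r.p_value for r in family])
        for r, q in zip(family, qs):
            r.q_value = float(q)


def multi_protein_presence(
        per_query_presence: Sequence[Mapping[str, bool]]) -> dict[str, bool]:
    """Samples count as positive only when every queried protein is present."""
    if not per_query_presence:
        raise ValueError("need at least one query presence vector")
    samples = set().union(*(m.keys() for m in per_query_presence))
    return {s: all(m.get(s, False) for m in per_query_presence)
            for s in sorted(samples)}


def function_positive_fraction(positive_genomes: Iterable[str],
                               abundances: pd.DataFrame,
                               tolerance: float = 1e-6) -> pd.Series:
    """Per-individual cumulative relative abundance of positive genomes.

    ``abundances`` is a genome (rows) x individual (columns) relative-
    abundance matrix with non-negative entries and column sums <= 1.
    """
    if (abundances.values < 0).any():
        raise ValueError("negative abundance value")
    col_sums = abundances.sum(axis=0)
    if (col_sums > 1 + tolerance).any():
        raise ValueError("per-individual abundances sum to > 1")
    positive = set(positive_genomes)
    missing = positive - set(abundances.index)
    if missing:
        logger.warning("%d positive genome(s) absent from abundance matrix: "
                       "%s", len(missing), sorted(missing)[:5])
    keep = [g for g in abundances.index if g in positive]
    if not keep:
        return pd.Series(0.0, index=abundances.columns)
    return abundances.loc[keep].sum(axis=0)


@dataclass(frozen=True)
class TaxonomicRange:
    n_species: int
    n_genera: int
    n_families: int
    n_phyla: int

    @property
    def shared(self) -> bool:
        """Widely shared: present in >= 10 species spanning >= 2 phyla."""
        return self.n_species >= 10 and self.n_phyla >= 2


def taxonomic_range(member_genomes: Iterable[str],
                    genome_taxonomy: Mapping[str, Sequence[str]],
                    ) -> TaxonomicRange:
    """Distinct species/genus/family/phylum counts among carrier genomes.

    ``genome_taxonomy`` maps genome id to (species, genus, family, phylum);
    genomes without taxonomy are skipped with a warning.
    """
    species, genera, families, phyla = set(), set(), set(), set()
    for g in member_genomes:
        tax = genome_taxonomy.get(g)
        if tax is None:
            logger.warning("genome %s has no taxonomy — skipped", g)
            continue
        s, ge, fa, ph = tax
        species.add(s)
        genera.add(ge)
        families.add(fa)
        phyla.add(ph)
    return TaxonomicRange(len(species), len(genera), len(families),
                          len(phyla))
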