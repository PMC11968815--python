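"""Seeded fixture generators that make every module testable offline.

Contigs carry planted genes built from a start "runway" (an upstream
in-frame alternative initiator with no intervening stops) plus a downstream
in-frame ATG, so simulated start-shift errors always yield valid same-stop
variants — exactly the conflicts the consensus merge must resolve.  Planted
edge-partial, sub-minimum-length, and decoy (spurious but valid) genes
exercise the filters.  Every generator ships its ground truth; outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import Contig, get_table, reverse_complement
from .expression import AlignmentCounts
from .predictions import GenePrediction

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

__all__ = [
    "ToolErrorModel",
    "SimulationConfig",
    "PlantedGene",
    "make_contigs",
    "simulate_tool_outputs",
    "make_protein_families",
    "make_ecology_fixture",
    "make_expression_fixture",
    "EcologyFixture",
]


@dataclass(frozen=True)
class ToolErrorModel:
    """Per-tool error probabilities."""

    miss: float = 0.0
    start_shift: float = 0.0
    spurious: float = 0.0  # probability of reporting each planted decoy

    def __post_init__(self) -> None:
        for p in (self.miss, self.start_shift, self.spurious):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 5
    genes_per_contig: int = 4
    body_codons: tuple[int, int] = (20, 60)  # inclusive range
    table_id: int = 11
    runway_codons: int = 6
    n_edge_genes: int = 0
    n_short_genes: int = 0
    n_decoys: int = 0
    internal_tga: bool = False
    spacer_len: tuple[int, int] = (20, 40)
    tools: dict[str, ToolErrorModel] = field(default_factory=dict)
    # ecology fixture
    n_case: int = 20
    n_control: int = 20
    base_rate: float = 0.3
    odds_ratio: float = 1.0
    disease: str = "CD"
    n_genomes: int = 10
    n_individuals: int = 15
    concentration: float = 1.0
    # expression fixture
    n_samples: int = 4
    total_reads: int = 100_000


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one planted gene.

    ``alt_spans`` are the engineered same-stop start variants (upstream
    runway initiator and downstream in-frame ATG) used for simulated
    start-shift errors.  ``kind`` is one of gene/edge/short/decoy.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    table_id: int
    kind: str = "gene"
    alt_spans: tuple[tuple[int, int], ...] = ()

    @property
    def stop_position(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    def as_prediction(self, tool: str,
                      span: tuple[int, int] | None = None) -> GenePrediction:
        start, end = span if span is not None else (self.start, self.end)
        return GenePrediction(self.contig_id, start, end, self.strand, tool)


def _safe_codon(rng: np.random.Generator, table, forbid_tga: bool = False) -> str:
    while True:
        codon = "".join(_NT[i] for i in rng.integers(0, 4, 3))
        if codon in table.stop_codons:
            continue
        if forbid_tga and codon == "TGA":
            continue
        return codon


def _build_gene(rng: np.random.Generator, table_id: int, body_codons: int,
                runway_codons: int, internal_tga: bool = False,
                ) -> tuple[str, int, int]:
    """Return (sequence, main start offset, downstream start offset).

    Layout on the coding strand: runway ATG + safe codons, the annotated
    ATG, a body of non-stop codons containing a planted in-frame ATG (and
    optionally TGA, for table-4 fixtures), and a stop codon.  Offsets are
    0-based nucleotide offsets of the annotated and downstream starts.
    """
    table = get_table(table_id)
    # TGA in the runway/body would put a table-11 stop upstream when the
    # same sequence is re-read under table 11; forbid it unless asked for.
    forbid = not internal_tga
    runway = ["ATG"] + [_safe_codon(rng, table, forbid)
                        for _ in range(runway_codons - 1)]
    body = [_safe_codon(rng, table, forbid) for _ in range(body_codons)]
    down_at = body_codons // 2
    body[down_at] = "ATG"
    if internal_tga:
        if "TGA" in table.stop_codons:
            raise ValueError(
                f"internal TGA requested but TGA is a stop in table {table_id}")
        body[down_at + 1] = "TGA"
    stop = sorted(table.stop_codons)[rng.integers(0, len(table.stop_codons))]
    seq = "".join(runway) + "ATG" + "".join(body) + stop
    main_offset = 3 * runway_codons
    down_offset = main_offset + 3 + 3 * down_at
    return seq, main_offset, down_offset


def _spacer(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_NT[i] for i in rng.integers(0, 4, n))


def make_contigs(cfg: SimulationConfig,
                 ) -> tuple[list[Contig], list[PlantedGene]]:
    """Generate contigs with planted genes and their ground truth.

    Regular genes land on random strands between random spacers; the first
    ``n_edge_genes`` contigs additionally carry a gene whose start codon
    sits in the first (forward) or last (reverse) three contig bases;
    short (<21 nt) genes and decoys are spread round-robin over contigs.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.genes_per_contig < 0 or cfg.n_contigs < 1:
        raise ValueError("infeasible geometry")
    contigs: list[Contig] = []
    truth: list[PlantedGene] = []
    extra_short = _round_robin(cfg.n_short_genes, cfg.n_contigs)
    extra_decoy = _round_robin(cfg.n_decoys, cfg.n_contigs)
    for ci in range(cfg.n_contigs):
        cid = f"contig_{ci:04d}"
        parts: list[str] = []
        pos = 0  # 0-based length so far

        if ci < cfg.n_edge_genes:
            # forward edge gene flush with the contig start (start codon at 1)
            seq, main_off, down_off = _build_gene(
                rng, cfg.table_id, int(rng.integers(cfg.body_codons[0], cfg.body_codons[1] + 1)),
                runway_codons=1)
            parts.append(seq)
            truth.append(PlantedGene(cid, 1, len(seq), "+", cfg.table_id,
                                     kind="edge",
                                     alt_spans=((1, len(seq)),)))
            pos = len(seq)

        n_regular = cfg.genes_per_contig
        n_short = extra_short[ci]
        n_decoy = extra_decoy[ci]
        kinds = (["gene"] * n_regular + ["short"] * n_short
                 + ["decoy"] * n_decoy)
        for kind in kinds:
            parts.append(_spacer(rng, *cfg.spacer_len))
            pos = sum(map(len, parts))
            if kind == "short":
                table = get_table(cfg.table_id)
                stop = sorted(table.stop_codons)[0]
                seq = "ATG" + "".join(
                    _safe_codon(rng, table, True) for _ in range(4)) + stop
                main_off, down_off = 0, None
            else:
                seq, main_off, down_off = _build_gene(
                    rng, cfg.table_id, int(rng.integers(cfg.body_codons[0], cfg.body_codons[1] + 1)),
                    cfg.runway_codons, internal_tga=cfg.internal_tga)
            strand = "+" if rng.random() < 0.5 else "-"
            seg = seq if strand == "+" else reverse_complement(seq)
            parts.append(seg)
            s0, e0 = pos + 1, pos + len(seq)  # full runway span, forward
            if strand == "+":
                span = (s0 + main_off, e0)
                alts = () if down_off is None else ((s0, e0),
                                                    (s0 + down_off, e0))
            else:
                span = (s0, e0 - main_off)
                alts = () if down_off is None else ((s0, e0),
                                                    (s0, e0 - down_off))
            truth.append(PlantedGene(cid, span[0], span[1], strand,
                                     cfg.table_id, kind=kind, alt_spans=alts))
        parts.append(_spacer(rng, *cfg.spacer_len))

        if ci < cfg.n_edge_genes:
            # reverse edge gene flush with the contig end
            seq, _m, _d = _build_gene(
                rng, cfg.table_id, int(rng.integers(cfg.body_codons[0], cfg.body_codons[1] + 1)),
                runway_codons=1)
            pos = sum(map(len, parts))
            parts.append(reverse_complement(seq))
            truth.append(PlantedGene(cid, pos + 1, pos + len(seq), "-",
                                     cfg.table_id, kind="edge",
                                     alt_spans=((pos + 1, pos + len(seq)),)))
        contigs.append(Contig(cid, "".join(parts)))
    return contigs, truth


def _round_robin(total: int, bins: int) -> list[int]:
    out = [total // bins] * bins
    for i in range(total % bins):
        out[i] += 1
    return out


def simulate_tool_outputs(truth: Sequence[PlantedGene],
                          error_model: Mapping[str, ToolErrorModel],
                          seed: int = 0,
                          ) -> dict[str, list[GenePrediction]]:
    """Simulate each tool's prediction list from the planted truth.

    Non-decoy genes are missed with probability ``miss``, otherwise
    reported either at the true span or (with probability ``start_shift``,
    when the gene has engineered variants) at a same-stop alternative
    start.  Each decoy is reported with probability ``spurious``.
    """
    rng = np.random.default_rng(seed)
    outputs: dict[str, list[GenePrediction]] = {}
    for tool in sorted(error_model):
        em = error_model[tool]
        preds: list[GenePrediction] = []
        for gene in truth:
            if gene.kind == "decoy":
                if rng.random() < em.spurious:
                    preds.append(gene.as_prediction(tool))
                continue
            if rng.random() < em.miss:
                continue
            if gene.alt_spans and len(gene.alt_spans) > 1 \
                    and rng.random() < em.start_shift:
                span = gene.alt_spans[rng.integers(0, len(gene.alt_spans))]
                preds.append(gene.as_prediction(tool, span))
            else:
                preds.append(gene.as_prediction(tool))
        outputs[tool] = preds
    return outputs


# ---------------------------------------------------------------------------
# protein families


def make_protein_families(n_families: int, members_per_family: int,
                          rep_len: int = 120, substitution_rate: float = 0.05,
                          n_noise: int = 0, noise_len: tuple[int, int] = (30, 150),
                          seed: int = 0,
                          ) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Planted protein families with an exact substitution budget.

    Each family has one representative (strictly the longest member) and
    ``members_per_family - 1`` members carrying exactly
    ``round(rate * len)`` substitutions at evenly spaced interior
    positions, so identity to the representative is deterministic.
    Optional unrelated noise sequences are appended.  Returns
    (id -> sequence, family id -> member ids including the representative).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    families: dict[str, list[str]] = {}
    for fi in range(n_families):
        rep = "".join(AA_ALPHABET[i]
                      for i in rng.integers(0, 20, rep_len))
        fam_id = f"fam{fi}"
        rep_id = f"{fam_id}_rep"
        seqs[rep_id] = rep
        families[fam_id] = [rep_id]
        for mi in range(members_per_family - 1):
            mlen = rep_len - 1 - (mi % 3)
            base = rep[:mlen]
            n_sub = round(substitution_rate * mlen)
            positions = _even_positions(mlen, n_sub)
            chars = list(base)
            for p in positions:
                old = chars[p]
                chars[p] = AA_ALPHABET[(AA_ALPHABET.index(old) + 1) % 20]
            mid = f"{fam_id}_m{mi}"
            seqs[mid] = "".join(chars)
            families[fam_id].append(mid)
    for ni in range(n_noise):
        nlen = int(rng.integers(noise_len[0], noise_len[1] + 1))
        seqs[f"noise{ni}"] = "".join(AA_ALPHABET[i]
                                     for i in rng.integers(0, 20, nlen))
    return seqs, families


def _even_positions(length: int, n: int) -> list[int]:
    # interior positions, evenly spread, avoiding the 2 residues at each end
    if n == 0:
        return []
    lo, hi = 2, length - 3
    if n > hi - lo + 1:
        raise ValueError("substitution budget exceeds interior length")
    return sorted({lo + round(i * (hi - lo) / max(n - 1, 1))
                   for i in range(n)})


# ---------------------------------------------------------------------------
# ecology / expression fixtures


@dataclass
class EcologyFixture:
    metadata: pd.DataFrame
    presence: dict[str, bool]
    abundance: pd.DataFrame
    positive_genomes: list[str]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
        self.abundance.to_csv(out_dir / "abundance.tsv", sep="\t")
        pd.Series(self.presence, name="present").rename_axis("sample_id") \
            .astype(int).to_csv(out_dir / "presence.tsv", sep="\t")


def make_ecology_fixture(cfg: SimulationConfig) -> EcologyFixture:
    """Metadata, presence truth, and abundance matrix with a planted effect.

    A designated protein's presence follows ``base_rate`` in controls and
    the odds implied by ``odds_ratio`` in cases of ``cfg.disease``.
    Abundance columns are Dirichlet draws scaled below 1.
    """
    rng = np.random.default_rng(cfg.seed)
    odds0 = cfg.base_rate / (1 - cfg.base_rate)
    odds1 = cfg.odds_ratio * odds0
    p_case = odds1 / (1 + odds1)
    rows = []
    presence: dict[str, bool] = {}
    countries = ["NLD", "ISR", "GBR", "JPN"]
    for i in range(cfg.n_case + cfg.n_control):
        is_case = i < cfg.n_case
        sid = f"case_{i:03d}" if is_case else f"ctrl_{i - cfg.n_case:03d}"
        presence[sid] = bool(rng.random() < (p_case if is_case
                                             else cfg.base_rate))
        row = {
            "sample_id": sid,
            "age": int(rng.integers(18, 85)),
            "sex": "female" if rng.random() < 0.5 else "male",
            "bmi": float(np.round(rng.normal(25, 4), 1)),
            "country": countries[int(rng.integers(0, len(countries)))],
            "westernised": "yes" if rng.random() < 0.8 else "no",
            "smoker": "yes" if rng.random() < 0.25 else "no",
            "antibiotics": "yes" if rng.random() < 0.2 else "no",
        }
        for flag in ("CD", "UC", "CRC", "CDI", "T2D", "RA", "FL"):
            row[flag] = "no"
        if is_case:
            row[cfg.disease] = "yes"
        rows.append(row)
    metadata = pd.DataFrame(rows)

    genomes = [f"genome_{g:03d}" for g in range(cfg.n_genomes)]
    individuals = [f"indiv_{i:03d}" for i in range(cfg.n_individuals)]
    cols = {}
    for ind in individuals:
        weights = rng.dirichlet(np.full(cfg.n_genomes, cfg.concentration))
        cols[ind] = weights * rng.uniform(0.8, 1.0)
    abundance = pd.DataFrame(cols, index=genomes)
    n_pos = max(1, cfg.n_genomes // 3)
    positive = sorted(rng.choice(genomes, size=n_pos, replace=False))
    return EcologyFixture(metadata, presence, abundance, list(positive))


def make_expression_fixture(cfg: SimulationConfig,
                            cluster_members: Mapping[str, Sequence[str]],
                            rates: Mapping[str, float] | None = None,
                            ) -> list[AlignmentCounts]:
    """Per-sample read-count tables for expression tests.

    ``rates`` gives the Poisson mean read count per cluster per sample
    (default 5); reads are spread over the cluster's members.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for si in range(cfg.n_samples):
        per_target: dict[str, int] = {}
        for cid in sorted(cluster_members):
            lam = 5.0 if rates is None else rates[cid]
            n_reads = int(rng.poisson(lam))
            members = list(cluster_members[cid])
            for _ in range(n_reads):
                m = members[int(rng.integers(0, len(members)))]
                per_target[m] = per_target.get(m, 0) + 1
        aligned = sum(per_target.values())
        samples.append(AlignmentCounts(f"mtx_{si:03d}", cfg.total_reads,
                                       aligned, per_target))
    return samples
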