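"""Inference of regulatory edges from primary data.

Three independent routes produce edges for the network:

* **Seed matching** — canonical miRNA target sites in 3'UTRs. The seed is
  miRNA positions 2-8 (5' end, 1-based). A site in the mRNA (read 5'→3') is
  the reverse complement of the seed: an 8mer is the full 7-nt seed match
  followed by an opposing A, a 7mer-m8 is the 7-nt seed match alone, and a
  7mer-A1 matches positions 2-7 plus the opposing A. G:U wobble pairs are
  not accepted. Site efficacy (context score) is consumed as an input
  column and used only as a filter.

* **Consensus voting** — per-algorithm target predictions are combined and a
  (miRNA, gene) pair is accepted when at least ``min_votes`` of the N
  algorithms (default 8 of 10) predict it.

* **ChIP peak assignment** — a TF→feature edge is called when a binding peak
  overlaps the feature's promoter window (default 5 kb upstream to 1 kb
  downstream of the TSS, strand-aware) by at least one base. Coordinates are
  BED-style 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import DomainError, FormatError, ValidationError
from .regnet import EdgeType, RegEdge, RegulatoryNetwork

RNA_ALPHABET = frozenset("ACGU")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

SITE_8MER = "8mer"
SITE_7MER_M8 = "7mer-m8"
SITE_7MER_A1 = "7mer-A1"
#: most specific first
SITE_TYPES = (SITE_8MER, SITE_7MER_M8, SITE_7MER_A1)


def normalize_rna(sequence: str, what: str = "sequence") -> str:
    """Uppercase, convert T to U, and validate the alphabet."""
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValidationError(f"{what}: invalid characters {sorted(bad)}")
    return seq


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MirnaSequence:
    id: str
    sequence: str  # RNA, 5'->3'

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence",
                           normalize_rna(self.sequence, f"miRNA {self.id}"))
        if len(self.sequence) < 8:
            raise DomainError(
                f"miRNA {self.id}: length {len(self.sequence)} < 8; "
                "seed positions 1-8 undefined"
            )

    @property
    def seed(self) -> str:
        """Positions 2-8 (1-based), the 7-nt seed."""
        return self.sequence[1:8]

    def site_patterns(self) -> dict[str, str]:
        """UTR match strings (mRNA 5'->3') for each canonical site type."""
        m7m8 = reverse_complement_rna(self.seed)          # 7 nt
        m7a1 = reverse_complement_rna(self.sequence[1:7]) + "A"  # 7 nt
        return {
            SITE_8MER: m7m8 + "A",
            SITE_7MER_M8: m7m8,
            SITE_7MER_A1: m7a1,
        }


@dataclass(frozen=True)
class UtrRecord:
    transcript_id: str
    gene_id: str
    sequence: str  # RNA/DNA, T normalized to U

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"UTR {self.transcript_id}: empty sequence")
        object.__setattr__(
            self, "sequence",
            normalize_rna(self.sequence, f"UTR {self.transcript_id}"))


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    gene_id: str
    site_type: str
    start: int  # 0-based offset of the site's first base in the UTR
    context_score: float | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValidationError(f"unknown site type {self.site_type!r}")
        if self.start < 0:
            raise ValidationError("site start must be >= 0")

    @property
    def length(self) -> int:
        return 8 if self.site_type == SITE_8MER else 7


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_seed_sites(mirna: MirnaSequence, utr: UtrRecord) -> list[SeedSite]:
    """All canonical seed sites of one miRNA in one 3'UTR.

    Each locus is reported once with its most specific type
    (8mer > 7mer-m8 > 7mer-A1): a 7mer-m8 whose start coincides with an 8mer
    start, or a 7mer-A1 one base inside an 8mer, is subsumed by that 8mer.
    """
    pat = mirna.site_patterns()
    seq = utr.sequence
    starts8 = set(_find_all(seq, pat[SITE_8MER]))
    sites = [(s, SITE_8MER) for s in starts8]
    for s in _find_all(seq, pat[SITE_7MER_M8]):
        if s not in starts8:
            sites.append((s, SITE_7MER_M8))
    claimed = {s for s, _ in sites}
    for s in _find_all(seq, pat[SITE_7MER_A1]):
        if s - 1 not in starts8 and s not in claimed:
            sites.append((s, SITE_7MER_A1))
    return [SeedSite(mirna.id, utr.gene_id, t, s)
            for s, t in sorted(sites)]


def filter_by_context_score(
    pairs: Iterable[tuple[str, str, float]],
    threshold: float = -0.4,
    literal_greater: bool = False,
) -> list[tuple[str, str, float]]:
    """Retain (miRNA, gene, total context score) pairs passing the threshold.

    Context scores are more negative for stronger predicted repression, so
    the default comparator keeps scores ≤ threshold. ``literal_greater``
    switches to keeping scores strictly greater than the threshold for
    pipelines that define the cut the other way round.
    """
    if literal_greater:
        return [p for p in pairs if p[2] > threshold]
    return [p for p in pairs if p[2] <= threshold]


# ---------------------------------------------------------------------------
# Consensus voting over per-algorithm prediction tables


@dataclass
class PredictionMatrix:
    """(miRNA, gene) → subset of predicting algorithms."""

    algorithms: list[str]
    votes: dict[tuple[str, str], frozenset[str]]

    def __post_init__(self) -> None:
        if len(self.algorithms) < 1:
            raise ValidationError("prediction matrix needs >= 1 algorithm")
        if len(set(self.algorithms)) != len(self.algorithms):
            raise ValidationError("duplicate algorithm names")
        allowed = set(self.algorithms)
        for pair, voters in self.votes.items():
            extra = set(voters) - allowed
            if extra:
                raise ValidationError(
                    f"pair {pair}: votes from unknown algorithms {sorted(extra)}"
                )

    @property
    def n_algorithms(self) -> int:
        return len(self.algorithms)


def read_prediction_table(path, algorithms: Sequence[str] | None = None) -> PredictionMatrix:
    """Read a long-format TSV with columns algorithm, mirna, gene."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header line)")
    missing = {"algorithm", "mirna", "gene"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if algorithms is None:
        algorithms = sorted(df["algorithm"].unique())
    votes: dict[tuple[str, str], set[str]] = {}
    for row in df.itertuples(index=False):
        votes.setdefault((str(row.mirna), str(row.gene)), set()).add(str(row.algorithm))
    return PredictionMatrix(list(algorithms),
                            {k: frozenset(v) for k, v in votes.items()})


def consensus_vote(matrix: PredictionMatrix, min_votes: int = 8) -> set[tuple[str, str]]:
    """Pairs predicted by at least ``min_votes`` of the N algorithms."""
    if not 1 <= min_votes <= matrix.n_algorithms:
        raise DomainError(
            f"min_votes {min_votes} outside [1, {matrix.n_algorithms}]"
        )
    return {pair for pair, voters in matrix.votes.items()
            if len(voters) >= min_votes}


# ---------------------------------------------------------------------------
# ChIP peak -> promoter-window target assignment


@dataclass(frozen=True)
class ChipPeak:
    tf_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"peak {self.tf_id}@{self.chrom}: bad interval "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class TssAnnotation:
    feature_id: str
    feature_kind: str  # "gene" | "miRNA"
    chrom: str
    tss: int
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "miRNA"):
            raise ValidationError(
                f"{self.feature_id}: unknown feature kind {self.feature_kind!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.feature_id}: unknown strand symbol {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"{self.feature_id}: negative TSS")

    def promoter_window(self, upstream: int, downstream: int) -> tuple[int, int]:
        """Genomic half-open promoter interval, clipped at 0.

        For + strand: [tss - upstream, tss + downstream).
        For - strand the window is reflected: [tss - downstream, tss + upstream).
        """
        if self.strand == "+":
            lo, hi = self.tss - upstream, self.tss + downstream
        else:
            lo, hi = self.tss - downstream, self.tss + upstream
        return max(lo, 0), max(hi, 0)


def assign_peaks_to_targets(
    peaks: Sequence[ChipPeak],
    annotations: Sequence[TssAnnotation],
    upstream: int = 5000,
    downstream: int = 1000,
) -> list[RegEdge]:
    """TF→gene / TF→miRNA edges from peak-promoter overlap (≥ 1 bp).

    Duplicate (tf, feature) calls collapse to one edge; output is sorted by
    (edge_type, tf, feature) and independent of peak order.
    """
    if upstream < 0 or downstream < 0:
        raise DomainError("upstream/downstream must be >= 0")
    by_chrom: dict[str, list[ChipPeak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    net = RegulatoryNetwork()
    for ann in annotations:
        lo, hi = ann.promoter_window(upstream, downstream)
        if hi <= lo:
            continue
        et = EdgeType.TF_GENE if ann.feature_kind == "gene" else EdgeType.TF_MIR
        for peak in by_chrom.get(ann.chrom, ()):
            if peak.start < hi and lo < peak.end:  # >= 1 bp overlap
                net.add_edge(peak.tf_id, ann.feature_id, et,
                             provenance="chip-peak")
    return net.edges


# ---------------------------------------------------------------------------
# File readers


def read_mirna_fasta(path) -> list[MirnaSequence]:
    return [MirnaSequence(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def read_utr_fasta(path) -> list[UtrRecord]:
    """FASTA with headers ``>transcript_id gene_id`` (gene defaults to transcript)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        gene = parts[1] if len(parts) > 1 else rec.id
        out.append(UtrRecord(rec.id, gene, str(rec.seq)))
    return out


def read_peaks_bed(path) -> list[ChipPeak]:
    """BED3+1: chrom, start, end, tf_id (no header)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "tf_id"], dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df["tf_id"].isna().any():
        raise FormatError(f"{path}: expected 4 columns (chrom, start, end, tf_id)")
    return [ChipPeak(str(r.tf_id), str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def read_tss_table(path) -> list[TssAnnotation]:
    """TSV with header: feature_id, kind, chrom, tss, strand."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header line)")
    missing = {"feature_id", "kind", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    return [TssAnnotation(str(r.feature_id), str(r.kind), str(r.chrom),
                          int(r.tss), str(r.strand))
            for r in df.itertuples(index=False)]
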