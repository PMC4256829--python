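"""Corroboration of discovered FFLs with orthogonal evidence.

Two independent lines of evidence are counted: protein-protein interactions
among FFL target genes (confidence-filtered, STRING-style combined scores)
and differential-expression lists from patient samples. An FFL counts as
expression-confirmed when its miRNA is differentially expressed in either
direction (a strict-direction mode is available); its common target genes
are additionally annotated with gene-level DE membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import DomainError, FormatError, ValidationError
from .ffl_discovery import FFL
from .regnet import ExpressionList
from ._util import round_half_away


@dataclass(frozen=True)
class PpiRecord:
    gene_a: str
    gene_b: str
    confidence: float

    def __post_init__(self) -> None:
        if not self.gene_a < self.gene_b:
            raise ValidationError(
                f"PPI endpoints must be lexicographically ordered and "
                f"distinct: {self.gene_a!r}, {self.gene_b!r}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"PPI confidence {self.confidence} outside [0, 1]"
            )


def make_ppi_record(gene_a: str, gene_b: str, confidence: float) -> PpiRecord:
    """Canonicalize endpoint order before constructing the record."""
    if gene_a == gene_b:
        raise ValidationError(f"self-interaction {gene_a!r} not allowed")
    a, b = sorted((gene_a, gene_b))
    return PpiRecord(a, b, confidence)


def read_ppi_table(path) -> list[PpiRecord]:
    """TSV with header: gene_a, gene_b, confidence."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header line)")
    missing = {"gene_a", "gene_b", "confidence"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    out: list[PpiRecord] = []
    seen: set[tuple[str, str]] = set()
    for r in df.itertuples(index=False):
        rec = make_ppi_record(str(r.gene_a), str(r.gene_b), float(r.confidence))
        if (rec.gene_a, rec.gene_b) not in seen:
            seen.add((rec.gene_a, rec.gene_b))
            out.append(rec)
    return out


def filter_ppi(records: Sequence[PpiRecord], threshold: float = 0.4) -> list[PpiRecord]:
    """Keep interactions with confidence strictly greater than the threshold."""
    return [r for r in records if r.confidence > threshold]


def count_ppi_among(genes: set[str], ppi: Sequence[PpiRecord]) -> tuple[int, int]:
    """(genes incident to ≥1 retained interaction, interaction count).

    Only interactions with both endpoints inside ``genes`` are counted;
    duplicate records are counted once.
    """
    kept = {(r.gene_a, r.gene_b) for r in ppi
            if r.gene_a in genes and r.gene_b in genes}
    incident = {g for pair in kept for g in pair}
    return len(incident), len(kept)


@dataclass
class ValidationReport:
    """Evidence summary for a set of FFLs."""

    n_ffls: int
    confirmed_ffls: list[str]           # FFL keys with a DE miRNA
    confirmed_mirnas: set[str]
    deg_overlap: set[str]               # FFL common genes that are DE
    genes_per_ffl_deg: dict[str, set[str]] = field(default_factory=dict)
    mapped_genes: int = 0               # FFL genes incident to >=1 kept PPI
    ppi_count: int = 0

    @property
    def n_confirmed(self) -> int:
        return len(self.confirmed_ffls)

    @property
    def confirmed_fraction(self) -> float:
        return self.n_confirmed / self.n_ffls if self.n_ffls else 0.0

    def summary(self) -> dict:
        return {
            "n_ffls": self.n_ffls,
            "n_confirmed_ffls": self.n_confirmed,
            "confirmed_fraction": self.confirmed_fraction,
            "n_confirmed_mirnas": len(self.confirmed_mirnas),
            "n_deg_overlap_genes": len(self.deg_overlap),
            "mapped_genes": self.mapped_genes,
            "ppi_count": self.ppi_count,
        }


def confirm_ffls_with_expression(
    ffls: Sequence[FFL],
    mirna_deg: ExpressionList,
    gene_deg: ExpressionList | None = None,
    required_direction: str | None = None,
) -> ValidationReport:
    """Mark FFLs whose miRNA is differentially expressed.

    By default either direction confirms; ``required_direction`` ("up" or
    "down") restricts to miRNAs moving that way. One miRNA with several TF
    partners confirms each of its FFLs. Gene-level DE lists only annotate
    the common target genes; they do not gate confirmation.
    """
    if mirna_deg.entity_kind != "miRNA":
        raise ValidationError("mirna_deg must be a miRNA expression list")
    if gene_deg is not None and gene_deg.entity_kind != "gene":
        raise ValidationError("gene_deg must be a gene expression list")
    if required_direction not in (None, "up", "down"):
        raise DomainError(f"unknown direction {required_direction!r}")

    confirmed, mirnas = [], set()
    genes_per_ffl: dict[str, set[str]] = {}
    all_deg_genes: set[str] = set()
    for f in ffls:
        direction = mirna_deg.entries.get(f.mirna_id)
        hit = direction is not None and (
            required_direction is None or direction == required_direction)
        if hit:
            confirmed.append(f.key)
            mirnas.add(f.mirna_id)
        if gene_deg is not None:
            overlap = {g for g in f.common_genes if g in gene_deg}
            genes_per_ffl[f.key] = overlap
            all_deg_genes |= overlap
    return ValidationReport(
        n_ffls=len(ffls),
        confirmed_ffls=confirmed,
        confirmed_mirnas=mirnas,
        deg_overlap=all_deg_genes,
        genes_per_ffl_deg=genes_per_ffl,
    )


def validate_ffls(
    ffls: Sequence[FFL],
    ppi: Sequence[PpiRecord],
    mirna_deg: ExpressionList,
    gene_deg: ExpressionList | None = None,
    ppi_threshold: float = 0.4,
    required_direction: str | None = None,
) -> ValidationReport:
    """Full validation: expression confirmation plus PPI counting among all
    FFL common target genes."""
    report = confirm_ffls_with_expression(ffls, mirna_deg, gene_deg,
                                          required_direction)
    ffl_genes = set().union(*(f.common_genes for f in ffls)) if ffls else set()
    kept = filter_ppi(ppi, ppi_threshold)
    report.mapped_genes, report.ppi_count = count_ppi_among(ffl_genes, kept)
    return report


def mean_targets_per_mirna(pair_count: int, mirna_count: int) -> int:
    """Average targeted genes per miRNA, rounded half away from zero."""
    if mirna_count < 1:
        raise DomainError("mirna_count must be >= 1")
    if pair_count < 0:
        raise DomainError("pair_count must be >= 0")
    return int(round_half_away(pair_count / mirna_count, 0))
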