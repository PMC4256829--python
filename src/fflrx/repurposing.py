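"""Drug-repurposing candidate nomination from FFL miRNAs.

A drug becomes a repurposing candidate when it is known to perturb the
expression of at least one miRNA belonging to a significant FFL. Filters
restrict to approved drugs, optionally exclude boxed-warning labels, and
optionally require the drug's effect direction to oppose the miRNA's
disease direction (a drug that downregulates a disease-upregulated miRNA).
Candidate sets are tested for over-representation of ATC level-1
therapeutic categories with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .errors import ConfigurationError, DomainError, FormatError, ValidationError
from .ffl_discovery import FFL
from .regnet import ExpressionList
from ._util import round_half_away

logger = logging.getLogger("fflrx")

ATC_LEVEL1 = frozenset("ABCDGHJLMNPRSV")


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    approved: bool
    boxed_warning: bool
    atc_level1: frozenset[str]
    indication: str = ""

    def __post_init__(self) -> None:
        bad = set(self.atc_level1) - ATC_LEVEL1
        if bad:
            raise ValidationError(
                f"drug {self.drug_id}: unknown ATC level-1 codes {sorted(bad)}"
            )


@dataclass(frozen=True)
class DrugMirnaEffect:
    drug_id: str
    mirna_id: str
    direction: str  # "up" | "down"
    source: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValidationError(
                f"effect {self.drug_id}->{self.mirna_id}: direction must be "
                f"up or down, got {self.direction!r}"
            )


@dataclass
class RepurposingCandidate:
    drug_id: str
    supporting_mirnas: set[str]
    supporting_ffls: set[str]
    direction_matched: dict[str, bool] = field(default_factory=dict)
    safety_note: str = ""

    def __post_init__(self) -> None:
        if not self.supporting_mirnas or not self.supporting_ffls:
            raise ValidationError(
                f"candidate {self.drug_id}: needs >= 1 supporting miRNA and FFL"
            )


def read_drug_registry(path) -> dict[str, DrugRecord]:
    """TSV: drug_id, name, approved, boxed_warning, atc_level1, indication."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header line)")
    required = {"drug_id", "name", "approved", "boxed_warning", "atc_level1"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    out: dict[str, DrugRecord] = {}
    for r in df.itertuples(index=False):
        atc = frozenset(c for c in str(r.atc_level1).split(",") if c and c != "nan")
        indication = str(getattr(r, "indication", "") or "")
        out[str(r.drug_id)] = DrugRecord(
            str(r.drug_id), str(r.name),
            _parse_bool(r.approved), _parse_bool(r.boxed_warning),
            atc, indication if indication != "nan" else "")
    return out


def read_drug_effects(path) -> list[DrugMirnaEffect]:
    """TSV: drug_id, mirna_id, direction, source; duplicates collapsed."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (expected a header line)")
    missing = {"drug_id", "mirna_id", "direction"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    out, seen = [], set()
    for r in df.itertuples(index=False):
        source = str(getattr(r, "source", "") or "")
        key = (str(r.drug_id), str(r.mirna_id), source)
        if key in seen:
            continue
        seen.add(key)
        out.append(DrugMirnaEffect(str(r.drug_id), str(r.mirna_id),
                                   str(r.direction), source))
    return out


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise FormatError(f"cannot parse boolean value {value!r}")


def nominate_candidates(
    ffls: Sequence[FFL],
    effects: Sequence[DrugMirnaEffect],
    registry: Mapping[str, DrugRecord],
    require_approved: bool = True,
    exclude_boxed: bool = False,
    require_direction_match: bool = False,
    mirna_deg: ExpressionList | None = None,
) -> list[RepurposingCandidate]:
    """Drugs with at least one qualifying effect on an FFL miRNA.

    With ``require_direction_match`` the drug must move the miRNA opposite
    to its disease direction (needs ``mirna_deg``). Output is deduplicated
    by drug and ordered by drug_id.
    """
    if not ffls:
        raise DomainError("no FFLs supplied")
    if require_direction_match and mirna_deg is None:
        raise ConfigurationError(
            "require_direction_match needs a miRNA expression list"
        )
    ffls_by_mirna: dict[str, set[str]] = {}
    for f in ffls:
        ffls_by_mirna.setdefault(f.mirna_id, set()).add(f.key)

    per_drug: dict[str, RepurposingCandidate] = {}
    for eff in effects:
        if eff.mirna_id not in ffls_by_mirna:
            continue
        drug = registry.get(eff.drug_id)
        if drug is None:
            logger.warning("effect references unknown drug %r; skipped", eff.drug_id)
            continue
        if require_approved and not drug.approved:
            continue
        if exclude_boxed and drug.boxed_warning:
            continue
        matched = False
        if mirna_deg is not None:
            disease_dir = mirna_deg.entries.get(eff.mirna_id)
            matched = disease_dir is not None and disease_dir != eff.direction
        if require_direction_match and not matched:
            continue
        cand = per_drug.get(eff.drug_id)
        if cand is None:
            per_drug[eff.drug_id] = RepurposingCandidate(
                drug_id=eff.drug_id,
                supporting_mirnas={eff.mirna_id},
                supporting_ffls=set(ffls_by_mirna[eff.mirna_id]),
                direction_matched={eff.mirna_id: matched},
                safety_note="boxed warning" if drug.boxed_warning else "",
            )
        else:
            cand.supporting_mirnas.add(eff.mirna_id)
            cand.supporting_ffls |= ffls_by_mirna[eff.mirna_id]
            cand.direction_matched[eff.mirna_id] = (
                cand.direction_matched.get(eff.mirna_id, False) or matched)
    return [per_drug[d] for d in sorted(per_drug)]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise DomainError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        raise DomainError("at least one margin must be positive")
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    return min(max(p, 0.0), 1.0)


def atc_enrichment(
    candidates: Iterable[RepurposingCandidate | str],
    background: Mapping[str, DrugRecord],
    alpha: float = 0.01,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-ATC-letter 2x2 Fisher tests of candidates against the registry.

    For each ATC level-1 letter present in the registry the table is
    (in-category vs not) x (candidate vs non-candidate). Drugs with several
    letters contribute to each letter's test. By default raw p-values are
    compared with ``alpha`` (no multiplicity correction); ``adjust=True``
    applies BH across letters first.
    """
    cand_ids = {c.drug_id if isinstance(c, RepurposingCandidate) else str(c)
                for c in candidates}
    unknown = cand_ids - set(background)
    if unknown:
        raise ValidationError(
            f"candidates not in the registry: {sorted(unknown)[:5]}"
        )
    letters = sorted({l for d in background.values() for l in d.atc_level1})
    n_cand = len(cand_ids)
    n_bg = len(background)
    rows = []
    for letter in letters:
        in_cat = {d for d, rec in background.items() if letter in rec.atc_level1}
        a = len(in_cat & cand_ids)
        b = n_cand - a
        c = len(in_cat) - a
        d = (n_bg - n_cand) - c
        rows.append({
            "atc": letter, "candidate_count": a,
            "background_count": len(in_cat),
            "p": fisher_exact_2x2(a, b, c, d),
        })
    df = pd.DataFrame(rows, columns=["atc", "candidate_count",
                                     "background_count", "p"])
    if adjust and len(df):
        from .ffl_discovery import benjamini_hochberg

        df["p_adj"] = benjamini_hochberg(df["p"].tolist())
        df["significant"] = df["p_adj"] < alpha
    else:
        df["significant"] = df["p"] < alpha
    return df


def confirmation_percentage(confirmed: int, total: int) -> float:
    """Percent of candidates with external support, one decimal place."""
    if total < 1:
        raise DomainError("total must be >= 1")
    if not 0 <= confirmed <= total:
        raise DomainError("confirmed must lie in [0, total]")
    return round_half_away(100.0 * confirmed / total, 1)


def candidates_to_frame(candidates: Sequence[RepurposingCandidate],
                        registry: Mapping[str, DrugRecord] | None = None) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rec = registry.get(c.drug_id) if registry else None
        rows.append({
            "drug_id": c.drug_id,
            "name": rec.name if rec else "",
            "supporting_mirnas": ";".join(sorted(c.supporting_mirnas)),
            "supporting_ffls": ";".join(sorted(c.supporting_ffls)),
            "n_direction_matched": sum(c.direction_matched.values()),
            "safety_note": c.safety_note,
            "atc_level1": ",".join(sorted(rec.atc_level1)) if rec else "",
        })
    return pd.DataFrame(rows, columns=["drug_id", "name", "supporting_mirnas",
                                       "supporting_ffls", "n_direction_matched",
                                       "safety_note", "atc_level1"])
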