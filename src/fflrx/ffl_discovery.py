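"""Co-regulation enrichment and feed-forward-loop enumeration.

For every (miRNA, TF) pair that shares at least one target gene inside a
common gene universe, the overlap is scored with the upper cumulative
hypergeometric tail

    p = P(X >= k) = 1 - sum_{i=0}^{k-1} C(n_mir, i) C(Total - n_mir, n_tf - i)
                                        / C(Total, n_tf)

where ``n_mir`` and ``n_tf`` are the regulators' target counts within the
universe, ``Total`` is the universe size and ``k`` the observed overlap.
Benjamini-Hochberg step-up correction controls the FDR across the tested
pairs, and significant pairs are expanded into feed-forward loops of three
categories depending on the regulator-regulator wiring:

* miRNA-FFL   — miRNA represses the TF (miRNA→TF), no TF→miRNA edge;
* TF-FFL      — TF drives the miRNA (TF→miRNA), no miRNA→TF edge;
* composite   — miRNA and TF regulate each other reciprocally.

In every category both regulators must share at least one common target
gene; the categories are mutually exclusive per pair by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ValidationError
from .regnet import EdgeType, RegulatoryNetwork


def hypergeometric_overlap_p(n_mir: int, n_tf: int, k: int, total: int) -> float:
    """Upper-tail cumulative hypergeometric probability P(X >= k).

    X is the overlap between a fixed set of ``n_mir`` marked genes and a
    uniformly drawn set of ``n_tf`` genes out of ``total``.
    """
    if k < 0 or k > min(n_mir, n_tf):
        raise DomainError(f"k={k} outside [0, min({n_mir}, {n_tf})]")
    if max(n_mir, n_tf) > total:
        raise DomainError(
            f"target counts ({n_mir}, {n_tf}) exceed universe size {total}"
        )
    if total <= 0:
        raise DomainError("universe must be non-empty")
    # sf(k-1) = P(X >= k); computed by scipy in log space
    p = float(hypergeom.sf(k - 1, total, n_mir, n_tf))
    return min(max(p, 0.0), 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values, in the input order, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


class FflCategory(str, enum.Enum):
    MIRNA_FFL = "MIRNA_FFL"
    TF_FFL = "TF_FFL"
    COMPOSITE_FFL = "COMPOSITE_FFL"


@dataclass(frozen=True)
class EnrichmentResult:
    mirna_id: str
    tf_id: str
    n_mir: int
    n_tf: int
    total: int
    k: int
    p_raw: float
    p_adj: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n_mir, self.n_tf):
            raise ValidationError("overlap k outside [0, min(n_mir, n_tf)]")
        if max(self.n_mir, self.n_tf) > self.total:
            raise ValidationError("target counts exceed universe size")
        if self.p_adj < self.p_raw - 1e-12:
            raise ValidationError("adjusted p below raw p")


@dataclass(frozen=True)
class FFL:
    category: FflCategory
    mirna_id: str
    tf_id: str
    common_genes: frozenset[str]
    enrichment: EnrichmentResult

    def __post_init__(self) -> None:
        if not self.common_genes:
            raise ValidationError("FFL requires a non-empty common gene set")

    @property
    def key(self) -> str:
        return f"{self.category.value}:{self.mirna_id}:{self.tf_id}"


def _universe(network: RegulatoryNetwork, universe_mode: str) -> tuple[
        dict[str, set[str]], dict[str, set[str]], set[str]]:
    mir_targets = network.targets_by_source(EdgeType.MIR_GENE)
    tf_targets = network.targets_by_source(EdgeType.TF_GENE)
    if not mir_targets or not tf_targets:
        raise DomainError(
            "network needs at least one miRNA→gene and one TF→gene edge"
        )
    mir_union = set().union(*mir_targets.values())
    tf_union = set().union(*tf_targets.values())
    if universe_mode == "intersection":
        universe = mir_union & tf_union
    elif universe_mode == "union":
        universe = mir_union | tf_union
    else:
        raise DomainError(f"unknown universe_mode {universe_mode!r}")
    if not universe:
        raise DomainError("empty gene universe; no co-regulated genes")
    return mir_targets, tf_targets, universe


def _pair_category(network: RegulatoryNetwork, m: str, t: str) -> FflCategory | None:
    m_to_t = network.has_edge(m, t, EdgeType.MIR_TF)
    t_to_m = network.has_edge(t, m, EdgeType.TF_MIR)
    if m_to_t and t_to_m:
        return FflCategory.COMPOSITE_FFL
    if m_to_t:
        return FflCategory.MIRNA_FFL
    if t_to_m:
        return FflCategory.TF_FFL
    return None


def score_pairs(
    network: RegulatoryNetwork,
    universe_mode: str = "intersection",
    bh_family: str = "pooled",
) -> list[EnrichmentResult]:
    """Hypergeometric overlap enrichment for every co-targeting pair.

    The gene universe is the intersection (default: genes both repressed by
    some miRNA and driven by some TF) or union of the two target-gene
    unions. Pairs with zero overlap inside the universe cannot form an FFL
    and are excluded from the BH family. ``bh_family`` is either "pooled"
    (one correction across all tested pairs) or "per_category" (separate
    families per regulator-regulator wiring class, pairs with no
    miRNA↔TF wiring forming their own family).
    """
    if bh_family not in ("pooled", "per_category"):
        raise DomainError(f"unknown bh_family {bh_family!r}")
    mir_targets, tf_targets, universe = _universe(network, universe_mode)
    total = len(universe)
    tested: list[tuple[str, str, int, int, int, float]] = []
    for m in sorted(mir_targets):
        m_set = mir_targets[m] & universe
        if not m_set:
            continue
        for t in sorted(tf_targets):
            t_set = tf_targets[t] & universe
            k = len(m_set & t_set)
            if k < 1:
                continue  # cannot form an FFL; excluded from the BH family
            p = hypergeometric_overlap_p(len(m_set), len(t_set), k, total)
            tested.append((m, t, len(m_set), len(t_set), k, p))
    if not tested:
        return []
    if bh_family == "pooled":
        adj = benjamini_hochberg([t[5] for t in tested])
    else:
        adj = [0.0] * len(tested)
        groups: dict[object, list[int]] = {}
        for i, (m, t, *_rest) in enumerate(tested):
            groups.setdefault(_pair_category(network, m, t), []).append(i)
        for idx in groups.values():
            sub = benjamini_hochberg([tested[i][5] for i in idx])
            for i, a in zip(idx, sub):
                adj[i] = a
    return [
        EnrichmentResult(m, t, nm, nt, total, k, p, min(a, 1.0))
        for (m, t, nm, nt, k, p), a in zip(tested, adj)
    ]


def enumerate_ffls(
    network: RegulatoryNetwork,
    enrichment: Sequence[EnrichmentResult],
    alpha: float = 0.05,
) -> list[FFL]:
    """Significant (p_adj < alpha) pairs expanded into categorized FFLs.

    ``common_genes`` are all genes targeted by both regulators in the
    network (not restricted to the enrichment universe). Output order is
    (category, p_adj, mirna, tf).
    """
    mir_targets = network.targets_by_source(EdgeType.MIR_GENE)
    tf_targets = network.targets_by_source(EdgeType.TF_GENE)
    out: list[FFL] = []
    for res in enrichment:
        if not res.p_adj < alpha:
            continue
        category = _pair_category(network, res.mirna_id, res.tf_id)
        if category is None:
            continue
        common = mir_targets.get(res.mirna_id, set()) & \
            tf_targets.get(res.tf_id, set())
        if not common:
            continue
        out.append(FFL(category, res.mirna_id, res.tf_id,
                       frozenset(common), res))
    order = {c: i for i, c in enumerate(FflCategory)}
    out.sort(key=lambda f: (order[f.category], f.enrichment.p_adj,
                            f.mirna_id, f.tf_id))
    return out


# ---------------------------------------------------------------------------
# Tabular output


ENRICHMENT_COLUMNS = ["mirna", "tf", "n_mir", "n_tf", "k", "total",
                      "p_raw", "p_adj"]

FFL_TABLE_COLUMNS = ["category", "mirna", "tf", "n_mir", "n_tf", "k",
                     "total", "p_raw", "p_adj", "common_genes"]


def write_enrichment_table(results: Sequence[EnrichmentResult], path,
                           header_comment: str | None = None) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [{"mirna": r.mirna_id, "tf": r.tf_id, "n_mir": r.n_mir,
          "n_tf": r.n_tf, "k": r.k, "total": r.total,
          "p_raw": r.p_raw, "p_adj": r.p_adj} for r in results],
        columns=ENRICHMENT_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_enrichment_table(path) -> list[EnrichmentResult]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    return [EnrichmentResult(str(r.mirna), str(r.tf), int(r.n_mir),
                             int(r.n_tf), int(r.total), int(r.k),
                             float(r.p_raw), float(r.p_adj))
            for r in df.itertuples(index=False)]


def ffls_to_frame(ffls: Sequence[FFL]):
    import pandas as pd

    rows = []
    for f in ffls:
        e = f.enrichment
        rows.append({
            "category": f.category.value, "mirna": f.mirna_id, "tf": f.tf_id,
            "n_mir": e.n_mir, "n_tf": e.n_tf, "k": e.k, "total": e.total,
            "p_raw": e.p_raw, "p_adj": e.p_adj,
            "common_genes": ";".join(sorted(f.common_genes)),
        })
    return pd.DataFrame(rows, columns=FFL_TABLE_COLUMNS)


def write_ffl_table(ffls: Sequence[FFL], path, header_comment: str | None = None) -> None:
    df = ffls_to_frame(ffls)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_ffl_table(path) -> list[FFL]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    ffls = []
    for r in df.itertuples(index=False):
        enr = EnrichmentResult(str(r.mirna), str(r.tf), int(r.n_mir),
                               int(r.n_tf), int(r.total), int(r.k),
                               float(r.p_raw), float(r.p_adj))
        genes = frozenset(str(r.common_genes).split(";"))
        ffls.append(FFL(FflCategory(r.category), str(r.mirna), str(r.tf),
                        genes, enr))
    return ffls
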