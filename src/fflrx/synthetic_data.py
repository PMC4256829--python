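"""Seeded generators for every pipeline input, with planted ground truth.

The generator emulates the statistical structure of the real data sources
(target-prediction tables, ChIP peak sets, STRING-style PPI confidences,
differential-expression lists, drug registries) without attempting their
size or identifier vocabularies. Its central design property is that the
planted signal is *exact*:

* planted FFL regulators carry exactly their planted target profiles —
  background edges are sprinkled only among non-planted regulators — so a
  planted composite's five-gene overlap is maximally surprising under the
  hypergeometric null and category labels can never be upgraded by noise;
* 3'UTR background sequence is rejection-sampled until the only seed
  matches, for any generated miRNA, are the planted sites;
* PPI confidences are drawn above the filter threshold inside planted FFL
  gene sets and below it elsewhere;
* differential-expression coverage and drug wiring use exact counts, so
  recovery tests are deterministic given the seed.

A single integer seed drives everything: ``numpy.random.SeedSequence(seed)``
is spawned into six independent child streams (network, predictions,
sequences, peaks, validation tables, drug tables), so regenerating one
input class never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .edge_inference import (
    SITE_TYPES, ChipPeak, MirnaSequence, PredictionMatrix, TssAnnotation,
    UtrRecord, find_seed_sites,
)
from .errors import ConfigurationError, FflrxError
from .ffl_discovery import FflCategory
from .regnet import EdgeType, RegulatoryNetwork, write_edge_table
from .validation import PpiRecord, make_ppi_record


@dataclass
class SynthesisConfig:
    """All knobs of the generator; defaults are the reference study conditions."""

    seed: int = 0
    # network size
    n_mirnas: int = 20
    n_tfs: int = 20
    n_genes: int = 200
    # planted motifs
    n_planted_composite: int = 10
    n_planted_mirna_ffl: int = 3
    n_planted_tf_ffl: int = 3
    genes_per_planted_ffl: int = 5
    background_edge_density: float = 0.05
    # prediction matrix
    n_algorithms: int = 10
    algo_sensitivity: float = 0.9
    algo_fpr: float = 0.05
    # sequences
    utr_length: int = 120
    mirna_length: int = 22
    context_score_range: tuple[float, float] = (-1.2, -0.45)
    # validation tables
    ppi_signal_conf_range: tuple[float, float] = (0.5, 0.9)
    ppi_noise_conf_range: tuple[float, float] = (0.0, 0.4)
    ppi_noise_density: float = 0.005
    deg_coverage: float = 0.6
    # drug tables
    n_drugs: int = 60
    n_true_drugs: int = 12
    frac_approved: float = 0.7
    frac_boxed: float = 0.15
    enriched_atc: str = "L"
    atc_skew: float = 0.7
    # ChIP peaks
    peak_width: int = 200
    n_decoy_peaks: int = 20
    promoter_upstream: int = 5000
    promoter_downstream: int = 1000

    def __post_init__(self) -> None:
        for name in ("background_edge_density", "algo_sensitivity", "algo_fpr",
                     "deg_coverage", "frac_approved", "frac_boxed", "atc_skew",
                     "ppi_noise_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        n_planted = (self.n_planted_composite + self.n_planted_mirna_ffl
                     + self.n_planted_tf_ffl)
        if n_planted > min(self.n_mirnas, self.n_tfs):
            raise ConfigurationError(
                f"{n_planted} planted FFLs need {n_planted} distinct miRNAs "
                f"and TFs; only {self.n_mirnas}/{self.n_tfs} available"
            )
        if self.genes_per_planted_ffl > self.n_genes:
            raise ConfigurationError("genes_per_planted_ffl exceeds n_genes")
        if self.n_true_drugs > self.n_drugs:
            raise ConfigurationError("n_true_drugs exceeds n_drugs")

    # -- identifier vocabularies -----------------------------------------

    @property
    def mirna_ids(self) -> list[str]:
        return [f"mir-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def drug_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(1, self.n_drugs + 1)]

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(6)
        names = ("network", "predictions", "sequences", "peaks",
                 "validation", "drugs")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class PlantedFfl:
    category: str
    mirna: str
    tf: str
    genes: list[str]


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks."""

    planted_ffls: list[PlantedFfl] = field(default_factory=list)
    true_mir_gene_pairs: list[list[str]] = field(default_factory=list)
    planted_sites: list[dict] = field(default_factory=list)
    signal_ppi_pairs: list[list[str]] = field(default_factory=list)
    deg_mirnas: dict = field(default_factory=dict)   # id -> direction
    deg_genes: dict = field(default_factory=dict)
    true_drugs: list[str] = field(default_factory=list)
    decoy_drugs: list[str] = field(default_factory=list)
    drug_links: dict = field(default_factory=dict)   # drug -> [mirnas]

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(f.mirna, f.tf) for f in self.planted_ffls}

    def planted_ffls_of(self, category: FflCategory | str) -> list[PlantedFfl]:
        cat = FflCategory(category).value
        return [f for f in self.planted_ffls if f.category == cat]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["planted_ffls"] = [PlantedFfl(**p) for p in raw["planted_ffls"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# Network with planted motifs


def generate_network(config: SynthesisConfig,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[RegulatoryNetwork, GroundTruth]:
    """Planted FFLs over a sparse random background.

    Each planted FFL gets a dedicated (miRNA, TF) pair and
    ``genes_per_planted_ffl`` co-targeted genes. Background edges of every
    class appear independently with probability ``background_edge_density``
    but never originate from a planted regulator, keeping planted target
    profiles (and hence category labels and overlap statistics) exact.
    """
    rng = config.streams()["network"] if rng is None else rng
    mirnas, tfs, genes = config.mirna_ids, config.tf_ids, config.gene_ids
    truth = GroundTruth()
    net = RegulatoryNetwork()

    n_planted = (config.n_planted_composite + config.n_planted_mirna_ffl
                 + config.n_planted_tf_ffl)
    planted_m = [mirnas[i] for i in
                 rng.choice(config.n_mirnas, n_planted, replace=False)]
    planted_t = [tfs[i] for i in
                 rng.choice(config.n_tfs, n_planted, replace=False)]
    categories = ([FflCategory.COMPOSITE_FFL] * config.n_planted_composite
                  + [FflCategory.MIRNA_FFL] * config.n_planted_mirna_ffl
                  + [FflCategory.TF_FFL] * config.n_planted_tf_ffl)
    for cat, m, t in zip(categories, planted_m, planted_t):
        gs = sorted(genes[i] for i in
                    rng.choice(config.n_genes, config.genes_per_planted_ffl,
                               replace=False))
        if cat in (FflCategory.COMPOSITE_FFL, FflCategory.MIRNA_FFL):
            net.add_edge(m, t, EdgeType.MIR_TF, provenance="planted")
        if cat in (FflCategory.COMPOSITE_FFL, FflCategory.TF_FFL):
            net.add_edge(t, m, EdgeType.TF_MIR, provenance="planted")
        for g in gs:
            net.add_edge(m, g, EdgeType.MIR_GENE, provenance="planted")
            net.add_edge(t, g, EdgeType.TF_GENE, provenance="planted")
        truth.planted_ffls.append(PlantedFfl(cat.value, m, t, gs))

    planted_mirna_set = set(planted_m)
    planted_tf_set = set(planted_t)
    dens = config.background_edge_density

    def sprinkle(sources, targets, edge_type, excluded_sources):
        draw = rng.random((len(sources), len(targets)))
        for i, s in enumerate(sources):
            if s in excluded_sources:
                continue
            for j, t in enumerate(targets):
                if s == t or draw[i, j] >= dens:
                    continue
                if not net.has_edge(s, t, edge_type):
                    net.add_edge(s, t, edge_type, provenance="background")

    sprinkle(mirnas, genes, EdgeType.MIR_GENE, planted_mirna_set)
    sprinkle(mirnas, tfs, EdgeType.MIR_TF, planted_mirna_set)
    sprinkle(tfs, mirnas, EdgeType.TF_MIR, planted_tf_set)
    sprinkle(tfs, genes, EdgeType.TF_GENE, planted_tf_set)

    truth.true_mir_gene_pairs = sorted(
        [s, t] for (s, t, et) in (e.key for e in net.edges)
        if et is EdgeType.MIR_GENE
    )
    return net, truth


# ---------------------------------------------------------------------------
# Prediction matrices


def simulate_prediction_matrix(
    rng: np.random.Generator,
    algorithms: list[str],
    true_pairs: list[tuple[str, str]],
    false_pairs: list[tuple[str, str]],
    sensitivity: float,
    fpr: float,
) -> PredictionMatrix:
    """Independent per-algorithm Bernoulli votes on true and false pairs."""
    votes: dict[tuple[str, str], set[str]] = {}
    for algo in algorithms:
        t_mask = rng.random(len(true_pairs)) < sensitivity
        f_mask = rng.random(len(false_pairs)) < fpr
        for pair, hit in zip(true_pairs, t_mask):
            if hit:
                votes.setdefault(pair, set()).add(algo)
        for pair, hit in zip(false_pairs, f_mask):
            if hit:
                votes.setdefault(pair, set()).add(algo)
    return PredictionMatrix(list(algorithms),
                            {k: frozenset(v) for k, v in votes.items()})


def generate_prediction_matrix(config: SynthesisConfig, truth: GroundTruth,
                               rng: np.random.Generator | None = None,
                               ) -> PredictionMatrix:
    rng = config.streams()["predictions"] if rng is None else rng
    algorithms = [f"algo{i:02d}" for i in range(1, config.n_algorithms + 1)]
    true_pairs = [tuple(p) for p in truth.true_mir_gene_pairs]
    true_set = set(true_pairs)
    false_pairs = [(m, g) for m in config.mirna_ids for g in config.gene_ids
                   if (m, g) not in true_set]
    return simulate_prediction_matrix(rng, algorithms, true_pairs, false_pairs,
                                      config.algo_sensitivity, config.algo_fpr)


# ---------------------------------------------------------------------------
# Sequences with planted seed sites

_BASES = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, length))


def generate_sequences(config: SynthesisConfig, truth: GroundTruth,
                       rng: np.random.Generator | None = None,
                       max_attempts: int = 500,
                       ) -> tuple[list[MirnaSequence], list[UtrRecord], list[dict]]:
    """miRNAs, 3'UTRs and the planted-site table.

    One site (random canonical type) is planted per true miRNA→gene pair in
    that gene's UTR. Background sequence is rejection-sampled per UTR until
    re-scanning against *all* generated miRNAs recovers exactly the planted
    sites, so recovery tests are exact rather than probabilistic. miRNA
    seeds are kept pairwise distinct for the same reason.
    """
    rng = config.streams()["sequences"] if rng is None else rng
    mirnas: list[MirnaSequence] = []
    seen_seeds: set[str] = set()
    for mid in config.mirna_ids:
        for _ in range(max_attempts):
            cand = MirnaSequence(mid, _random_rna(rng, config.mirna_length))
            if cand.seed not in seen_seeds:
                seen_seeds.add(cand.seed)
                mirnas.append(cand)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise FflrxError("could not draw a miRNA with a unique seed")
    by_id = {m.id: m for m in mirnas}

    targets_per_gene: dict[str, list[str]] = {}
    for m, g in truth.true_mir_gene_pairs:
        targets_per_gene.setdefault(g, []).append(m)

    utrs: list[UtrRecord] = []
    site_rows: list[dict] = []
    lo, hi = config.context_score_range
    for gene in config.gene_ids:
        site_mirnas = sorted(targets_per_gene.get(gene, []))
        length = max(config.utr_length, 16 * max(len(site_mirnas), 1))
        utr, planted = _assemble_utr(rng, gene, site_mirnas, by_id, mirnas,
                                     length, max_attempts)
        utrs.append(utr)
        for mid, stype, start in planted:
            site_rows.append({
                "mirna": mid, "gene": gene, "site_type": stype, "start": start,
                "context_score": float(np.round(rng.uniform(lo, hi), 3)),
            })
    truth.planted_sites = site_rows
    return mirnas, utrs, site_rows


def _assemble_utr(rng, gene, site_mirnas, by_id, all_mirnas, length,
                  max_attempts):
    """Build one UTR whose only seed matches are the planted ones."""
    n = len(site_mirnas)
    for _ in range(max_attempts):
        planted: list[tuple[str, str, int]] = []
        if n == 0:
            seq = _random_rna(rng, length)
        else:
            block = length // n
            parts, cursor = [], 0
            for i, mid in enumerate(site_mirnas):
                stype = str(rng.choice(SITE_TYPES))
                pattern = by_id[mid].site_patterns()[stype]
                block_end = length if i == n - 1 else (i + 1) * block
                start = int(rng.integers(cursor, block_end - len(pattern) + 1))
                parts.append(_random_rna(rng, start - cursor))
                parts.append(pattern)
                planted.append((mid, stype, start))
                cursor = start + len(pattern)
            parts.append(_random_rna(rng, length - cursor))
            seq = "".join(parts)
        utr = UtrRecord(gene, gene, seq)
        if _matches_exactly(utr, all_mirnas, planted):
            return utr, planted
    raise FflrxError(
        f"UTR assembly for {gene} failed to converge after {max_attempts} "
        f"attempts; try a longer utr_length"
    )


def _matches_exactly(utr, all_mirnas, planted) -> bool:
    expected = {(mid, stype, start) for mid, stype, start in planted}
    found = set()
    for m in all_mirnas:
        for site in find_seed_sites(m, utr):
            found.add((site.mirna_id, site.site_type, site.start))
            if len(found) > len(expected):
                return False
    return found == expected


# ---------------------------------------------------------------------------
# ChIP peaks + TSS annotation

_FEATURE_SPACING = 20000
_FIRST_TSS = 10000


def generate_peaks(config: SynthesisConfig, network: RegulatoryNetwork,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[ChipPeak], list[TssAnnotation]]:
    """One peak inside the promoter window of every true TF edge target,
    plus decoy peaks in intergenic gaps (never inside any window)."""
    rng = config.streams()["peaks"] if rng is None else rng
    features = [(g, "gene") for g in config.gene_ids] \
        + [(m, "miRNA") for m in config.mirna_ids]
    annotations = []
    tss_of: dict[str, TssAnnotation] = {}
    for i, (fid, kind) in enumerate(features):
        ann = TssAnnotation(fid, kind, "chr1", _FIRST_TSS + i * _FEATURE_SPACING,
                            "+" if rng.random() < 0.5 else "-")
        annotations.append(ann)
        tss_of[fid] = ann
    up, down, width = (config.promoter_upstream, config.promoter_downstream,
                       config.peak_width)
    peaks: list[ChipPeak] = []
    edges = [e for e in network.edges
             if e.edge_type in (EdgeType.TF_GENE, EdgeType.TF_MIR)]
    for e in edges:
        lo, hi = tss_of[e.target].promoter_window(up, down)
        start = int(rng.integers(lo, hi - width + 1))
        peaks.append(ChipPeak(e.source, "chr1", start, start + width))
    # decoys live in the dead zone [tss+up+1k, tss+spacing-up-1k) of random
    # features, outside every promoter window
    gap_lo, gap_margin = up + down, up + down
    for _ in range(config.n_decoy_peaks):
        ann = annotations[int(rng.integers(0, len(annotations)))]
        offset = int(rng.integers(ann.tss + gap_lo,
                                  ann.tss + _FEATURE_SPACING - gap_margin - width))
        tf = config.tf_ids[int(rng.integers(0, config.n_tfs))]
        peaks.append(ChipPeak(tf, "chr1", offset, offset + width))
    return peaks, annotations


# ---------------------------------------------------------------------------
# Validation + drug tables


def generate_validation_and_drug_tables(
    config: SynthesisConfig, truth: GroundTruth,
    rng_validation: np.random.Generator | None = None,
    rng_drugs: np.random.Generator | None = None,
) -> dict:
    """PPI records, DEG lists, drug registry and drug→miRNA effect table.

    PPI confidences are drawn from the signal range for every within-FFL
    gene pair and from the noise range for background pairs. DEG lists
    cover an exact ``deg_coverage`` fraction of planted-FFL miRNAs and
    genes. True drugs are wired to planted composite-FFL miRNAs (and are
    always approved); decoys are wired to non-FFL miRNAs only.
    """
    rngs = config.streams() if rng_validation is None or rng_drugs is None else {}
    rng_v = rngs["validation"] if rng_validation is None else rng_validation
    rng_d = rngs["drugs"] if rng_drugs is None else rng_drugs

    # --- PPI ---
    signal_pairs: set[tuple[str, str]] = set()
    for f in truth.planted_ffls:
        gs = sorted(f.genes)
        for i, a in enumerate(gs):
            for b in gs[i + 1:]:
                signal_pairs.add((a, b))
    s_lo, s_hi = config.ppi_signal_conf_range
    n_lo, n_hi = config.ppi_noise_conf_range
    ppi: list[PpiRecord] = [
        make_ppi_record(a, b, float(np.round(rng_v.uniform(s_lo, s_hi), 3)))
        for a, b in sorted(signal_pairs)
    ]
    genes = config.gene_ids
    n_possible = len(genes) * (len(genes) - 1) // 2
    n_noise = int(round(config.ppi_noise_density * n_possible))
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < n_noise:
        i, j = rng_v.integers(0, len(genes), 2)
        if i == j:
            continue
        pair = tuple(sorted((genes[i], genes[j])))
        if pair not in signal_pairs and pair not in chosen:
            chosen.add(pair)
    ppi += [make_ppi_record(a, b, float(np.round(rng_v.uniform(n_lo, n_hi), 3)))
            for a, b in sorted(chosen)]
    truth.signal_ppi_pairs = [list(p) for p in sorted(signal_pairs)]

    # --- DEG lists (exact coverage of planted miRNAs/genes) ---
    planted_mirnas = sorted({f.mirna for f in truth.planted_ffls})
    planted_genes = sorted({g for f in truth.planted_ffls for g in f.genes})

    def cover(ids: list[str], generator) -> dict[str, str]:
        k = int(round(config.deg_coverage * len(ids)))
        picked = sorted(ids[i] for i in
                        generator.choice(len(ids), k, replace=False))
        return {i: ("up" if generator.random() < 0.5 else "down")
                for i in picked}

    truth.deg_mirnas = cover(planted_mirnas, rng_v)
    truth.deg_genes = cover(planted_genes, rng_v)

    # --- drugs ---
    composite_mirnas = sorted({f.mirna for f in truth.planted_ffls
                               if f.category == FflCategory.COMPOSITE_FFL.value}) \
        or planted_mirnas
    ffl_mirnas = set(planted_mirnas)
    background_mirnas = sorted(set(config.mirna_ids) - ffl_mirnas)
    if not background_mirnas:
        raise ConfigurationError("no non-FFL miRNAs left for decoy drugs")

    drug_ids = config.drug_ids
    true_ids = drug_ids[: config.n_true_drugs]
    decoy_ids = drug_ids[config.n_true_drugs:]
    n_decoy_approved = int(round(config.frac_approved * len(decoy_ids)))
    approved = set(true_ids) | {
        decoy_ids[i] for i in
        rng_d.choice(len(decoy_ids), n_decoy_approved, replace=False)
    } if decoy_ids else set(true_ids)
    n_boxed = int(round(config.frac_boxed * len(drug_ids)))
    boxed = {drug_ids[i] for i in
             rng_d.choice(len(drug_ids), n_boxed, replace=False)}

    letters = sorted(set("ABCDGJLMNRSV"))
    registry_rows, effects = [], []
    links: dict[str, list[str]] = {}
    for did in drug_ids:
        is_true = did in true_ids
        if is_true and rng_d.random() < config.atc_skew:
            atc = {config.enriched_atc}
        else:
            atc = {letters[int(rng_d.integers(0, len(letters)))]}
        if rng_d.random() < 0.3:
            atc.add(letters[int(rng_d.integers(0, len(letters)))])
        registry_rows.append({
            "drug_id": did, "name": f"drug-{did.lower()}",
            "approved": did in approved, "boxed_warning": did in boxed,
            "atc_level1": ",".join(sorted(atc)),
            "indication": "synthetic indication",
        })
        pool = composite_mirnas if is_true else background_mirnas
        n_eff = int(rng_d.integers(1, min(3, len(pool)) + 1))
        wired = sorted(pool[i] for i in
                       rng_d.choice(len(pool), n_eff, replace=False))
        links[did] = wired
        for m in wired:
            effects.append({
                "drug_id": did, "mirna_id": m,
                "direction": "up" if rng_d.random() < 0.5 else "down",
                "source": "sm2mir-like",
            })
    truth.true_drugs = list(true_ids)
    truth.decoy_drugs = list(decoy_ids)
    truth.drug_links = links
    return {"ppi": ppi, "mirna_deg": truth.deg_mirnas,
            "gene_deg": truth.deg_genes, "drugs": registry_rows,
            "effects": effects}


# ---------------------------------------------------------------------------
# Bundle writer


def _write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _write_tsv(rows: list[dict], columns: list[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in columns) + "\n")


def generate_bundle(config: SynthesisConfig, outdir) -> GroundTruth:
    """Emit every pipeline input file plus ground_truth.json into a directory.

    Byte-identical across runs for a fixed config (seed included).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    streams = config.streams()

    net, truth = generate_network(config, streams["network"])
    for et, fname in ((EdgeType.MIR_GENE, "mir_gene.tsv"),
                      (EdgeType.MIR_TF, "mir_tf.tsv"),
                      (EdgeType.TF_MIR, "tf_mir.tsv"),
                      (EdgeType.TF_GENE, "tf_gene.tsv")):
        write_edge_table(net, out / fname, et)

    matrix = generate_prediction_matrix(config, truth, streams["predictions"])
    pred_rows = [{"algorithm": a, "mirna": m, "gene": g}
                 for (m, g), voters in sorted(matrix.votes.items())
                 for a in sorted(voters)]
    _write_tsv(pred_rows, ["algorithm", "mirna", "gene"], out / "predictions.tsv")

    mirnas, utrs, sites = generate_sequences(config, truth, streams["sequences"])
    _write_fasta([(m.id, m.sequence) for m in mirnas], out / "mirnas.fasta")
    _write_fasta([(f"{u.transcript_id} {u.gene_id}", u.sequence) for u in utrs],
                 out / "utrs.fasta")
    _write_tsv(sites, ["mirna", "gene", "site_type", "start", "context_score"],
               out / "sites.tsv")

    peaks, annotations = generate_peaks(config, net, streams["peaks"])
    with open(out / "peaks.bed", "w", encoding="utf-8") as fh:
        for p in sorted(peaks, key=lambda p: (p.chrom, p.start, p.tf_id)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_id}\n")
    _write_tsv([{"feature_id": a.feature_id, "kind": a.feature_kind,
                 "chrom": a.chrom, "tss": a.tss, "strand": a.strand}
                for a in annotations],
               ["feature_id", "kind", "chrom", "tss", "strand"],
               out / "tss.tsv")

    tables = generate_validation_and_drug_tables(
        config, truth, streams["validation"], streams["drugs"])
    _write_tsv([{"gene_a": r.gene_a, "gene_b": r.gene_b,
                 "confidence": r.confidence} for r in tables["ppi"]],
               ["gene_a", "gene_b", "confidence"], out / "ppi.tsv")
    _write_tsv([{"id": i, "direction": d}
                for i, d in sorted(tables["mirna_deg"].items())],
               ["id", "direction"], out / "mirna_deg.tsv")
    _write_tsv([{"id": i, "direction": d}
                for i, d in sorted(tables["gene_deg"].items())],
               ["id", "direction"], out / "gene_deg.tsv")
    _write_tsv(tables["drugs"],
               ["drug_id", "name", "approved", "boxed_warning", "atc_level1",
                "indication"], out / "drugs.tsv")
    _write_tsv(tables["effects"], ["drug_id", "mirna_id", "direction", "source"],
               out / "drug_effects.tsv")
    truth.to_json(out / "ground_truth.json")
    return truth
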