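# Methods

## Model and assumptions

`fflrx` treats gene regulation as a typed tripartite graph. Nodes carry
roles (miRNA, TF, gene); a TF always also carries the gene role because
TFs are protein-coding genes and may themselves be regulated targets, while
the miRNA role is exclusive of TF. Five edge classes are distinguished:
miRNA→gene and miRNA→TF (repression), TF→miRNA and TF→gene (transcriptional
regulation), and undirected gene–gene protein interactions stored with
lexicographically ordered endpoints. Identifier matching is exact and
case-sensitive; symbol normalization and alias resolution are assumed to
have happened upstream.

A feed-forward loop is a (miRNA m, TF t) pair plus a non-empty set of
common target genes, categorized by the m↔t wiring:

* **miRNA-FFL** — m→t present, t→m absent;
* **TF-FFL** — t→m present, m→t absent;
* **composite FFL** — both m→t and t→m.

The categories are mutually exclusive per pair by construction.

### Co-regulation significance

The null hypothesis for a pair is that the TF's target set within the
common gene universe is an unstructured draw: with `n_mir` and `n_tf` the
regulators' in-universe target counts, `Total` the universe size and `k`
the observed overlap, the p-value is the upper cumulative hypergeometric
tail P(X ≥ k), evaluated via the survival function of
`scipy.stats.hypergeom` (log-space internally). Adjusted p-values use
Benjamini–Hochberg step-up (through `statsmodels`); ties share the smallest
qualifying adjusted value and outputs are capped at 1.

Three conventions matter and are fixed as follows:

* **Tail bound.** The test sums to k−1, i.e. p = P(X ≥ k): observing *at
  least* the seen overlap. This is the standard enrichment tail; the
  alternative bound (sum to k) differs by one term and would make k = 0
  certain-but-tested.
* **Universe.** `Total` defaults to the *intersection* of the miRNA-repressed
  and TF-regulated gene unions — the genes that could possibly be
  co-regulated — with a `union` mode available. With a single miRNA and a
  single TF the intersection universe makes any overlap forced (p = 1);
  this is correct behaviour, not a defect: co-regulation is only surprising
  relative to targets that could have been missed.
* **BH family.** Pairs with k = 0 cannot form an FFL and are excluded from
  the family (they would only dilute the correction); the family is pooled
  across categories by default, with a per-category option.

Significance uses a strict comparison (p_adj < α, default α = 0.05).

### Edge inference

*Seed matching.* The seed is miRNA positions 2–8 (1-based, 5′ end). Site
patterns on the mRNA (read 5′→3′) are: 8mer = reverse complement of the
7-nt seed followed by A; 7mer-m8 = the 7-nt seed match alone; 7mer-A1 =
reverse complement of positions 2–7 followed by A. G:U wobble pairs are not
accepted. Overlapping calls at one locus resolve to the most specific type
(8mer > 7mer-m8 > 7mer-A1); a 7mer-m8 starting at an 8mer start, or a
7mer-A1 one base inside an 8mer, is subsumed. T and U are interchangeable
on input. Context scores are consumed as an input column (site efficacy
models are out of scope). The filter default keeps *total context score ≤
−0.4*, because context scores are more negative for stronger predicted
repression; a `literal_greater` flag switches to keeping scores > −0.4 for
pipelines that define the cut in the opposite direction. Both modes are
exposed because published descriptions of this filter are ambiguous; the
default follows score semantics rather than wording.

*Consensus voting.* A (miRNA, gene) pair is accepted when at least
`min_votes` (default 8) of the N prediction algorithms (default 10) list
it. The vote is monotone: raising `min_votes` never adds pairs. The
consensus set can either corroborate an existing edge set or replace it;
the pipeline exposes both uses rather than asserting one.

*ChIP peaks.* All coordinates are BED-style 0-based half-open. The promoter
window of a + strand feature with TSS t is [t − upstream, t + downstream);
on the − strand the window is reflected to genomic
[t − downstream, t + upstream). Defaults: upstream 5000 bp, downstream
1000 bp. A TF→feature edge is called on ≥ 1 bp overlap between a peak and
the window on the same chromosome; duplicate calls collapse.

### Validation and repurposing

PPI records keep a single combined confidence in [0, 1]; the filter is
strictly greater than the threshold (default 0.4). An FFL is
expression-confirmed when its miRNA appears in the miRNA DE list in either
direction (direction is recorded; a strict-direction mode exists). Gene DE
lists annotate the common targets but do not gate confirmation. A miRNA
shared by several FFLs confirms each of them.

A drug is nominated when it has at least one effect on an FFL miRNA and
passes the approval filter (boxed-warning exclusion and
direction-opposition matching are optional; direction matching requires the
miRNA DE list and keeps only drugs moving the miRNA against its disease
direction). ATC level-1 enrichment runs one two-sided Fisher exact test per
letter present in the registry — (in-category vs not) × (candidate vs
non-candidate) — at a raw cutoff of 0.01 with no multiplicity correction by
default (a BH option exists); drugs with several letters count once per
letter. The two-sided p sums all fixed-margin tables whose probability does
not exceed the observed table's (via `scipy.stats.fisher_exact`).

Two small statistics use round-half-away-from-zero (not banker's
rounding): mean targets per miRNA (nearest integer) and the confirmation
percentage (one decimal).

## Synthetic data: what it emulates, and what it does not

The generator produces every input the pipeline reads — edge TSVs,
per-algorithm prediction tables, miRNA/UTR FASTA with a planted-site table,
ChIP peaks + TSS annotation, PPI confidences, DEG lists, drug registry and
drug→miRNA effects — plus a `ground_truth.json` describing everything
planted. One integer seed is spawned (via `numpy.random.SeedSequence`) into
six independent streams (network, predictions, sequences, peaks,
validation tables, drugs), so the file set is byte-identical per seed and
regenerating one input class does not perturb the others.

Key design properties, chosen to make recovery tests exact rather than
probabilistic:

* **Planted profiles are exact.** Each planted FFL gets a dedicated
  (miRNA, TF) pair and its own co-targeted gene set. Background edges are
  Bernoulli per possible pair at `background_edge_density`, but never
  originate from a planted regulator. This both preserves category labels
  (a one-way FFL can never be upgraded to composite by noise) and keeps a
  planted 5-gene overlap maximally surprising: with clean profiles the
  planted pairs have hypergeometric tails around 10⁻⁶ after FDR, far below
  α, whereas background-inflated profiles would put them near the
  significance boundary and make recovery seed-dependent.
* **Rejection-sampled UTRs.** Background UTR sequence is resampled until
  scanning *every* generated miRNA against the assembled UTR recovers
  exactly the planted sites; miRNA seeds are drawn pairwise distinct.
  Planted-site recovery is therefore exact (no flaky false-positive
  tolerance).
* **Separated PPI confidence ranges.** Within-FFL gene pairs draw from
  (0.5, 0.9), background pairs from (0.0, 0.4), so the 0.4 filter retains
  exactly the signal interactions.
* **Exact counts where tests need them.** DE coverage selects
  round(coverage × n) planted regulators without replacement (0.6 of 15
  distinct miRNAs ⇒ exactly 9 confirmed FFLs); true drugs are always
  approved and wired only to planted composite miRNAs, decoys only to
  non-FFL miRNAs.

Reference conditions (the class defaults): 20 miRNAs, 20 TFs, 200 genes;
10 planted composite plus 3 + 3 one-way FFLs of 5 genes each; background
density 0.05 per edge class; 10 pseudo-algorithms at sensitivity 0.9 and
false-positive rate 0.05 with an 8-vote consensus; 120-nt UTRs, 22-nt
miRNAs; 60 drugs of which 12 true candidates, 70% of decoys approved, 15%
boxed warnings, ATC letter L enriched among true candidates with skew 0.7.
These sizes keep the full pipeline under a second while leaving ~100 genes
of head-room between planted overlaps and the background expectation.

What the generator does **not** emulate: real identifier vocabularies and
database sizes; correlated errors between prediction algorithms (votes are
independent Bernoulli, real algorithms share training signal); conservation
structure or composition bias in UTRs; PPI degree heterogeneity and
evidence-channel structure; dose- or tissue-dependence of drug–miRNA
effects. Passing recovery tests therefore demonstrates correctness of the
pipeline's logic and statistics under a controlled signal model, not
performance on any real disease dataset.

## Degenerate inputs and numerical edges

* Tanimoto similarity of two empty target sets is undefined and raises;
  miRNAs with empty target sets are dropped from similarity networks.
* Duplicate edges with conflicting scores keep the maximum-magnitude score
  (sign breaks exact ties) and log the collision; merging is associative,
  commutative and order-independent.
* Self-edges are rejected in every edge class.
* `hypergeometric_overlap_p` validates k ≤ min(n_mir, n_tf) ≤ total and
  clamps the scipy result into [0, 1]; k = 0 returns exactly 1.
* Empty p-value lists return empty; single-element BH is the identity.
* Fisher tables must have a positive grand total; negative or non-integer
  entries raise.

## Known limitations

* No null-model comparison against degree-preserving randomized networks;
  significance is overlap-based only.
* The enrichment test conditions on the network as given — uncertainty in
  the inferred edges (seed-match false positives, ChIP noise) is not
  propagated into the p-values.
* PPI validation counts interactions but does not test their enrichment
  against a random gene-set baseline.
* Literature/clinical-trial confirmation of candidates is an input
  annotation, never computed.
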