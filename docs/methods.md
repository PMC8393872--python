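# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `mirnet` pipeline.

## Pull-down enrichment model

The biotin pull-down design yields four sequencing libraries per experiment:
the pull-down and input lysate for the transfected miRNA and for a control
miRNA. Library-size differences are removed with median-of-ratios size
factors (the DESeq-style estimator, computed over genes with positive counts
in every library, on the raw ratio scale so that the even-count median is
the arithmetic mean of the two middle ratios). The per-gene statistic is the
log2 double ratio E_g = log2(((mir_pd+c)/(ctl_pd+c)) / ((mir_in+c)/(ctl_in+c)))
with a pseudocount c = 1 on normalized counts (configurable); dividing by
the input ratio cancels transcript abundance and any depletion of targets in
the transfected lysate.

Unbound transcripts put E_g in a unimodal distribution centred at 0; bound
transcripts form a right tail. "Right elbow" selection is operationalized as
μ + kσ with robust estimates μ = median, σ = 1.4826·MAD and k = 2: for a
zero-centred Gaussian of SD 0.475 — the visible spread of the assay's null —
this lands at 0.95 in log2, and on a pure null it selects the upper ~2.3%
tail. A Kneedle-style alternative (maximum distance between the right-tail
survival curve and its chord) is provided for distributions whose tail is
not Gaussian-like. Selection is closed (≥ cutoff) with ties kept.

## Expression selection and SILAC rollup

Transcript selection is a symmetric closed threshold at |log2FC| ≥ 0.5.
The proteome path models the SILAC label-swap design: per mix, peptide log2
ratios are shifted so the mix median is 0 (absorbing protein-mixing errors);
the two orientations of each peptide are averaged after sign alignment;
protein log2 ratio is the arithmetic mean of its peptide log2 ratios
(geometric mean of raw ratios); proteins with fewer than 3 distinct
quantified peptides are dropped. Significance is a two-sided one-sample
t-test of peptide log2 ratios against 0 with BH correction; a protein whose
peptides are identical but nonzero has no t statistic and is assigned the
smallest representable double with a `degenerate` flag. By default the
down/up calls use the fold-change threshold alone; the FDR filter is an
optional additional constraint.

## Overlap statistics

All list overlaps are one-sided hypergeometric upper tails
P(X ≥ k), X ~ Hypergeom(N, n1, n2), evaluated on an explicitly restricted
universe: the caller must first intersect each list with the set of genes
detectable by *all* experiments being compared, and passing an unrestricted
list is an error. This matters because the proteome detects roughly half the
genome; testing a transcriptome list against a proteome list on the full
gene universe would wildly overstate significance. Duplicate identifiers
are treated as an input error rather than silently de-duplicated.

## Seed-word scan

The scan is the occurrence-based hypergeometric word-enrichment model: the
urn holds every k-mer occurrence in the whole ranked UTR list (N balls, K of
them the word of interest); a leading window of the top t genes holds n
balls and k_obs occurrences of the word; the reported value is
−log10 P(X ≥ k_obs) when the over-representation tail is smaller and
+log10 P(X ≤ k_obs) otherwise, so positive means over-represented in the
window. Windows grow from `window_start` in steps of `window_step` until
they cover the list (500/500 by default; 100/100 for the shorter proteome
ranking), and at the full-list window every word's value is exactly 0.
Windows containing non-ACGT characters are skipped; scanning is forward-
strand and case-insensitive; −log10 p is floored at 320. One UTR per gene
(the longest; ties to the lexicographically smallest transcript id).
No Markov/composition correction is applied — the plain hypergeometric
model only.

Seed-match words follow the canonical site-type definitions from the miRNA
targeting literature (positions 1-based from the miRNA 5' end, rc = DNA
reverse complement): 6mer = rc(2–7), 7mer-m8 = rc(2–8), 7mer-A1 = rc(2–7)+A,
8mer = rc(2–8)+A, and a 5-mer core = rc(2–6). For miR-491-5p
(AGUGGGGAACCCUUCCAUGAGG) these are CCCCAC, TCCCCAC, CCCCACA, TCCCCACA and
CCCAC.

The per-word `flagged` indicator in the scan report uses a Bonferroni line
at α = 0.05 over all (word, window) cells of the landscape. Note that one
scan is one α-level family: on null data the *expected* number of flagged
words per scan is about 0.05, so a single null scan occasionally flags one
random word; what the statistic guarantees is familywise control, which is
what the test suite asserts (never a seed word under the null, and a total
flag count across several null runs within the Poisson bound implied by
α = 0.05 per family with an allowance for within-sequence word clumping).

Ranking direction is configurable and recorded in the output; the default
places the signal end first (most enriched, or most down-regulated, at the
top), so the seed-complementary word peaks near the number of true targets.

## Pathways and networks

ORA intersects every gene set with the detection universe before testing
(N = |universe|, m = |set ∩ universe|, n = |list|, k = |list ∩ set|) and
BH-adjusts across the collection. List merging produces each single
experiment, every leave-one-out union, and the full union; merged lists are
tested on the union of their contributing detection universes. By design
the overlap analyses use down-regulated lists only (candidate direct
targets), while ORA and the networks use both directions (full downstream
response) — the pipeline enforces this asymmetry.

Interaction tables are STRING-dialect (integer combined score 0–1000);
edges under 400 are dropped (closed threshold), self-loops removed, and
duplicate undirected pairs collapsed keeping the maximum score. Networks
are induced subgraphs: edges require both endpoints in the gene list, and
list members absent from the filtered interactome remain as degree-0 nodes
so mean connectivity 2E/V has a stable denominator. Hubs are ranked by
degree (distinct neighbors), ties broken by identifier.

## Synthetic data: what it emulates and what it does not

The generator plants one recoverable truth through all six input kinds.
Defaults define the study condition used throughout the tests and the
acceptance script: 5000 genes, 200 targets, 15 hubs.

- **UTRs** — i.i.d. nucleotides at GC 0.45, lengths ~ Normal(800, 160) nt
  floored at 50; each target UTR receives one planted copy of the 8-mer
  site word (site type and copy number configurable).
- **Pull-down counts** — per-gene log-normal baseline (log-mean ln 300,
  log-sd 1) shared by the four libraries, negative-binomial noise at fixed
  dispersion 0.1 (the literature-typical cell-line value; the count model
  is a package choice, not something the assay dictates), distinct library
  size factors (1.0, 1.3, 0.8, 1.1), and the miR pull-down mean multiplied
  by 8 for targets. An optional `input_depletion_log2` additionally lowers
  the targets' miR-input mean to emulate target degradation in the
  transfected lysate; it defaults to 0 so that the expected target-vs-rest
  separation equals log2(fold) exactly.
- **Expression** — transcript log2FC ~ Normal(−1, 0.3) for targets and
  Normal(0, 0.3) otherwise; protein-level truth likewise; a random half of
  the genome is undetected at the protein level (partial proteome
  coverage); each detected protein gets 3 + Poisson(2) peptides, two
  label-swap mixes, peptide noise SD 0.2 and a per-mix constant mixing
  error ~ Normal(0, 0.2) that scale normalization must remove.
- **Network** — Barabási–Albert backbone (3 edges per new node) over all
  genes; hubs are drawn from the targets (so they survive selection) and
  wired to extra random partners — at least 10 more than the backbone's
  maximum degree, 400 by default — which guarantees they beat the entire
  natural scale-free tail in the full graph and, because their extra edges
  are spread uniformly, makes their degree inside any induced list network
  scale with list size. This is also what reproduces the headline network
  ordering: the union list induces the best-connected network.
- **Gene sets** — 200 sets of 20–200 members; the first 10 draw half their
  members from the targets, the rest uniformly.

All randomness derives from a single seed through independent named
streams, so outputs are byte-identical under a fixed seed and each stage is
insensitive to another stage's draw count.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: realistic UTR composition (repeats, local GC
structure, real site-context effects), correlated detection biases between
platforms, peptide-level missingness correlated with abundance, true
pathway-structured networks (hub edges here are sociologically random), or
any identifier-mapping noise. Recovery rates on this generator are upper
bounds of a clean-signal regime, not forecasts for any particular dataset.

## Numerical and design choices

- Hypergeometric tails come from scipy and are clipped into (0, 1];
  −log10 p floored at 320.
- BH adjustment delegates to statsmodels behind `setstats.bh_adjust` and is
  cross-checked in the tests against a hand-rolled step-up.
- All selection thresholds are closed (≥); ties are kept; every ordering in
  the package has a deterministic tie-break (by identifier), so identical
  inputs give byte-identical outputs.
- Problem sizes in the tests and acceptance script (5000 genes, one null
  replicate set of three seeds, 500-replicate ORA uniformity check) were
  chosen to make every statistical assertion sharp at desk scale while the
  whole suite stays around a minute.
- The `evaluate` stage computes proteome recall against the *detectable*
  targets (those in the proteome universe), since no method can recover a
  protein that was never quantified.

## Known limitations

- The elbow cutoff assumes a unimodal, roughly symmetric null; heavy
  contamination by true signal (many targets at extreme enrichment) biases
  the MAD upward slightly.
- The scan's hypergeometric model treats k-mer occurrences as exchangeable;
  within-sequence clumping of self-overlapping words (homopolymers) makes
  their p-values mildly anticonservative.
- ORA treats gene sets as flat lists — no ontology-graph propagation or
  redundancy reduction.
- Transcript-level pull-down analysis, microarray preprocessing, spectral
  search and identifier mapping are upstream of this package's inputs by
  design.
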