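# Methods

This note documents the models, parameter choices and numerical conventions
behind `minicoi`, and what the synthetic data generator does and does not
emulate.

## Primer scoring and in-silico PCR

A degenerate primer is matched gaplessly against a same-length window of
the plus strand (reverse primers via their reverse complement, so the
primer's 3' terminus sits at the leftmost plus-strand position of its
footprint). A position mismatches when the observed base's IUPAC set does
not intersect the primer code's set; N matches everything. The weighted
score sums per-position penalties: 0.4 outside the 3' window, 1.0 inside
the last 5 bases, 3.0 at the terminal 3' base; a site is a hit at score
<= 1.0. These defaults emulate the "default parameters" of the microbial
primer-analysis tools this scheme derives from and are all configurable
(`ScoringParams`). Matching is gapless because the target locus shows no
length variation across the amplicon in mammals; indels therefore read as
non-hits rather than shifted hits.

In-silico PCR reports at most one amplicon per template: the best-scoring
compatible (forward strictly upstream, non-overlapping) pair of hits, ties
to the leftmost positions. The product runs from the first base of the
forward footprint through the last base of the reverse footprint
inclusive, so for the bundled 26 nt / 22 nt pair the 202 bp product holds
a 154 nt insert. Product lengths are validated against actual sequence,
never against primer-name arithmetic.

De novo design seeds on exact 5-mers present in >= 60% of targets, anchors
each target at the seed's first occurrence (discarding outliers beyond
+/- 10 nt of the median), accumulates per-position base frequencies over
the requested primer length, and emits the IUPAC code covering every base
at frequency >= 0.05. Candidates rank by (target coverage desc, exclusion
coverage asc, degeneracy asc). The degeneracy cap (512) applies to design
candidates only: published primers of any degeneracy are accepted, since
useful field primers exceed it (one bundled forward primer has degeneracy
576).

## Reference curation, clustering, trimming

Curation applies filters in the fixed order marker -> length -> ambiguity
-> taxonomy and logs the first failure per record. Two presets mirror the
two passes of a typical assay build: "design" (500-700 nt, ambiguity drop)
and "reference" (>= 500 nt, COI-5P, genus-or-deeper).

Pairwise identity is matching columns / alignment columns of a unit-cost
global alignment (edlib); length-equal near-identical sequences align
gaplessly under this metric, which is what centroid clustering of COI
fragments needs. Greedy clustering visits records longest-first (ties by
id) and joins the first centroid at identity >= t — a deterministic
stand-in for abundance/length-sorted greedy clustering whose exact internal
ordering published tools do not specify.

Trimming to the mini-barcode is primer-anchored (in-silico PCR semantics)
rather than alignment-column based: exact, dependency-free, and equivalent
for records containing the footprints; records lacking a footprint are
excluded and logged rather than imputed.

## Classifier

The bootstrap naive-Bayes word classifier follows the published
presence-based design: word size k = 8, B = 100 bootstrap trials, each
drawing ceil(W/8) of the query's W distinct words with replacement; the
word prior is P(w) = (n(w)+0.5)/(N+1) and the class conditional
P(w|S) = (m(w,S)+P(w))/(M(S)+1). Scoring is done in log space; words
absent from training contribute a species-independent numerator plus the
shared denominator, so only their count matters. Ties in species score
break lexicographically, making classification bit-reproducible for a
fixed seed (the RNG seed is part of the estimator's parameters, default
1). Training is at species level with rank rollup: the reference tool
trains at genus, but this assay is evaluated at species level too, so
species is the training leaf and genus/family/order confidences are
rollups of the species-level trial winners — which also guarantees
confidence monotonicity across ranks. The working acceptance threshold of
0.8 trades correctly classified sequences against false positives; the
threshold-sweep machinery exists precisely to choose it per study.

The top-hit classifier assigns the deepest rank unanimous across the
references tied (within `tie_epsilon`, default 0) at the best identity. It
is intentionally aggressive: with an untrained species in the query set it
commits to the nearest trained species where the Bayes classifier
abstains, which the test suite verifies as a higher false-positive rate.

## Read pipeline

Universal tails (ACCCAACTGAATGGAGC forward, ACGCACTTGACTTGTCTTC reverse)
plus primer are stripped from each mate's 5' end when found within the
first 3 offsets at weighted score <= 1.0; reads missing either primer are
rejected. Merging picks the overlap (>= 20 nt, mismatch rate <= 0.10)
maximizing matches between the forward read and the reverse complement of
the reverse read; agreements get consensus quality min(Q1+Q2, 45),
conflicts keep the higher-quality base at quality |Q1-Q2| (standard merger
behavior; the upstream tools specify only their names). Screening drops
contigs with ambiguous bases or length outside the expected insert length
+/- 10 nt, then exact dereplication with abundance counts.

Chimera flagging is a deliberately simplified two-parent model: candidate
parents are same-length uniques at >= 2x the query's abundance (capped at
the 20 most abundant); over ordered parent pairs and crossover points, the
best chimeric model must beat the best single parent by >= 3 matching
positions and reach 99% identity. It is validated on constructed bimeras
and is not a drop-in replacement for reference chimera detectors on real
noisy data.

Detection requires >= 10 classified reads AND >= 0.1% of the sample —
field reports describe trace detections only as "small proportions", so
these stand-ins are explicit, logged and configurable. The arthropod
off-target screen counts a hit only when the exclusion model accepts a
call at genus rank or deeper: an order-level forced-choice call against a
library that contains nothing else carries no evidence.

## Evaluation framework

Leave-out evaluation dereplicates at 100% identity, holds out ceil(p*n)
sequences uniformly at random (p = 0.05, 5 replicates, seeded), trains on
the rest and classifies the held-out amplicon regions. At each rank and
threshold a held-out sequence is exactly one of: correct (accepted at the
rank, right taxon), false positive (accepted, wrong taxon), false negative
(not accepted at the rank) — the partition identity correct+FP+FN = 100%
is asserted per cell. Held-out sequences whose species vanished from
training stay in the denominator, mirroring classification against
incomplete reference databases. The sweep (0.5-1.0, step 0.05; the
published range names no step) re-thresholds a single set of bootstrap
trials per query, so FP is non-increasing and FN non-decreasing in the
threshold by construction. Whether real pipelines subsample per-cluster or
uniformly is unspecified; uniform seeded sampling is used.

Panel resolution is leave-self-out top-hit over a one-barcode-per-species
panel: a species is species-resolved iff no other species carries an
identical barcode; shared barcodes are scored congener-shared or
cross-genus-shared from the tie set's genera. This is a within-panel
comparison; consulting external databases for ambiguous cases (as field
studies do) is out of scope, which the +/- 2 percentage point tolerance on
the panel benchmark reflects.

## Synthetic data generator

Reference worlds grow by hierarchical mutation from a random stop-free
coding root (658 nt, vertebrate mitochondrial code): root -> genus
ancestor (d = 0.12) -> species ancestor (0.05) -> individual (0.005)
expected substitutions per site, defaults chosen to reproduce the low
intraspecific / high interspecific divergence that makes COI a usable
barcode. Substitutions carry a 3:1 third-codon-position bias, never touch
the planted primer footprints (concrete resolutions of the bundled pair,
re-planted until stop-free), and never create in-frame stops. Pooled reads
are drawn multinomially from per-species template constructs (tail +
202 bp product + tail), with constant-Q33 substitution errors
(p ~ 5e-4/base) and no indels — matching the average quality of real
pooled-guano runs. Realized divergences are reported by
`divergence_summary`.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: PCR amplification bias (read proportions are not
claimed to track template proportions in the field), indel and homopolymer
errors, quality decay along reads, index hopping, NUMT contamination, and
the taxonomic sampling biases of public databases. The stand-in fixtures
(186-sequence/54-species validation set; 430-species panel planting 394
unique + 22 congener-shared + 14 cross-genus-shared barcodes; mixed
bat/arthropod design set; four-class arthropod exclusion library) are
constructions with the published structural properties: tests against them
are parameter-recovery checks of the toolkit's machinery, not reproductions
of database-dependent field numbers. Arthropod worlds derive from the same
ancestral root as the bat world (COI is homologous across phyla), which
gives the word-overlap structure the off-target screen property depends
on.

## Problem sizes and numerical choices

The default test worlds are small (3-6 genera x 3 species x 3-5
sequences); the mock-community experiment uses 20,000 read pairs and the
panel benchmark 430 species — sizes chosen so the full pathway exercises
every stage while a complete run stays interactive on one CPU. Degenerate
codons in the stop screen count as stops only when every resolution is a
stop (curation removes ambiguous references, so this path affects reads
only). All tie-breaks are deterministic (lexicographic or leftmost), all
randomness flows from explicit integer seeds, and repeated runs are
byte-identical.

## Known limitations

- The chimera model handles two equal-length parents only.
- Gapless primer matching cannot score indel-containing binding sites.
- Genus-level-only training records are accepted by the estimators but the
  pipeline wrappers train at species level.
- The greedy clustering is quadratic in centroid count and intended for
  library-scale (10^4) inputs, not raw read sets.
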