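# minicoi

A toolkit for building and evaluating **COI mini-barcode assays** for
species identification from degraded, non-invasive DNA sources such as bat
guano. Standard full-length DNA barcodes (the 658 bp COI-5P "Folmer"
region) amplify poorly from feces; a short (~200 bp) mini-barcode flanked
by degenerate primers amplifies reliably from degraded templates and scales
to pooled-sample amplicon sequencing, where a single pooled collection of
fecal pellets reveals every species that contributed to it.

The toolkit covers the full analytical pathway:

- **`minicoi.primers`** — degenerate (IUPAC) primers with weighted-mismatch
  site scoring (3'-end mismatches penalized more than 5'), in-silico PCR
  with product extraction, conserved-region de novo primer design against
  target and exclusion sequence sets, and per-taxon coverage reports. The
  published mini-barcode primer set ships bundled (`SFF_145f`/`SFF_351r`
  yield the 202 bp product: 26 nt + 154 nt insert + 22 nt).
- **`minicoi.reflib`** — reference-library curation (marker / length /
  ambiguity / taxonomy filters), greedy centroid clustering at an identity
  threshold, and primer-anchored trimming to the mini-barcode region.
- **`minicoi.classify`** — two sklearn-style estimators: a bootstrap
  naive-Bayes k-mer classifier and a top-hit identity classifier
  (see the model below).
- **`minicoi.readpipe`** — paired-end amplicon processing: universal-tail
  and primer stripping, overlap merging with quality consensus, ambiguity
  and length screening, dereplication, two-parent chimera flagging, and
  per-species sample profiles with an explicit detection rule.
- **`minicoi.evaluate`** — leave-out cross-validation with correct /
  false-positive / false-negative accounting per rank and confidence
  threshold, threshold sweeps, leave-self-out panel resolution, and
  mock-community sensitivity/specificity.
- **`minicoi.synthdata`** — a seeded generator of COI-like reference worlds
  (coding, stop-free, hierarchical divergence, conserved primer footprints)
  and pooled read sets with known truth, so every stage is testable without
  network access.
- **`minicoi` CLI** — `simulate`, `design`, `amplify`, `buildref`, `trim`,
  `classify`, `evaluate`, `sweep`, `resolve`, `pipeline`.

## The classification model

Training records, for word size $k=8$, which species contain each of the
distinct overlapping k-mers of their reference sequences (presence, not
frequency). With $N$ training sequences of which $n(w)$ contain word $w$,
and $M(S)$ sequences for species $S$ of which $m(w,S)$ contain $w$:

$$P(w) = \frac{n(w) + 0.5}{N + 1}, \qquad
  P(w\mid S) = \frac{m(w,S) + P(w)}{M(S) + 1}$$

A query with distinct word set $V$ is assigned the species maximizing
$\prod_{w \in V} P(w\mid S)$. Confidence is estimated by bootstrap: each of
$B=100$ trials re-scores a with-replacement sample of $\lceil |V|/8 \rceil$
of the query's words, and the confidence at a rank is the fraction of
trials whose winner agrees with the full-data candidate at that rank
(hence non-decreasing from species toward order). A call is *accepted* at
the deepest rank whose confidence reaches the working threshold
$c = 0.8$; everything else is unclassified. The top-hit classifier instead
assigns the deepest rank unanimous among the references tied at the best
global-alignment identity.

## Worked example

```bash
minicoi simulate --seed 19 --outdir sim --n-pairs 600 --proportions 0.34,0.33,0.33
# world: 36 records, 12 species; pool: 600 read pairs
minicoi trim --fasta sim/world.fasta --taxonomy sim/world.taxonomy.tsv \
    --insert-only --outdir trim
# trimmed 36 of 36 records
minicoi pipeline --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --library trim/trimmed.fasta --taxonomy trim/trimmed.taxonomy.tsv \
    --seed 19 --outdir run
# detected: Genus01 sp01, Genus01 sp02, Genus01 sp03
```

The three detected taxa are exactly the three species the pool was drawn
from: the reads were stripped of tails and primers, merged, screened,
dereplicated, chimera-checked, and classified at confidence 0.8; a species
is reported when it accrues at least 10 reads and 0.1% of the sample.
`run/profile.tsv` holds the per-species read counts and proportions and
`run/accounting.json` the per-stage read accounting. Every subcommand also
writes a `manifest.json` echoing its resolved configuration.

In the same way, `minicoi resolve` on a one-barcode-per-species panel
reports the fraction of species whose mini-barcode is unique. On the
toolkit's bundled synthetic 430-species panel (which plants 36 species
sharing barcodes):

```
species-resolved 91.6%  congener-shared 5.1%  cross-genus 3.3%
```

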