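# Methods

This document specifies the models and algorithms implemented in
`herbmark`, the parameter defaults and their rationale, the synthetic-data
generator that stands in for a sequencing run, and the numerical
conventions that make every result reproducible.

## 1. Problem

A multi-ingredient herbal product declares a list of 1–55 plant species.
DNA metabarcoding of the product amplifies one or more short barcode loci
(an ITS2-like nuclear marker and an rbcL-like plastid marker) from whatever
DNA survived processing, sequences the pooled amplicons as paired-end
reads, and asks, per product and rank (species, genus, family):

* which declared taxa were **identified** (declared and detected),
* which were **not identified** (declared but not detected), and
* which detections were **other detected** (present but undeclared —
  admixture, substitution or contamination).

A product is **authentic** when 100% of its listed taxa are identified at
both the family and the genus rank.

## 2. Pipeline stages

### 2.1 Read merging

The reverse read is reverse-complemented and slid over the forward read.
Both layouts (forward read leftmost, and the reverse-complemented mate
leftmost) are scanned, which makes merging symmetric under swapping the
pair; the overlap of at least `min_overlap = 30` nt maximizing the number
of matching bases wins (ties prefer the longer overlap).  Pairs whose best
overlap exceeds `max_mismatch_frac = 0.1` mismatches are rejected.
Consensus: agreeing bases get quality `min(q1 + q2, 41)`; disagreeing bases
take the higher-quality base with quality `|q1 − q2|`; an equal-quality
disagreement becomes `N` with quality 0 (the only choice symmetric under
swapping the reads).

### 2.2 Quality filtering and dereplication

Merged reads are kept when `150 ≤ length ≤ 600` and the expected-error
statistic `EE = Σ 10^(−Q/10) ≤ 1.0` (inclusive).  Note that under the
consensus rule above a single overlap disagreement between two similar-
quality bases contributes ≈ 1 expected error, so the filter discards most
reads carrying an overlap disagreement — conservative, and deliberate.
Surviving reads are collapsed to unique sequences with multiplicities,
sorted by decreasing abundance (ties lexicographic).

### 2.3 MOTU clustering

Unique sequences pooled over all samples are processed in decreasing
abundance.  Each joins the first existing centroid (in founding order)
with global identity ≥ 0.99, else founds a new MOTU.  Identity comes from
Needleman–Wunsch global alignment with match +1, mismatch −1, gap −2, end
gaps penalized; identity = matches / alignment columns of the optimal
alignment, with traceback ties broken diagonal → up → left.  Because tie
alignments can carry different match counts, each pair is canonicalized
(shorter, then lexicographically smaller, sequence first), making identity
symmetric by construction.  Pairs ≤ 128 nt use the full dynamic program;
longer pairs use a banded DP whose band starts at `2·|Δlen| + 16` and
doubles until the score stabilizes.

### 2.4 Taxonomic assignment

Each MOTU is classified by its centroid.  A UTAX/RDP-style classifier
scores every reference by the number of distinct query 8-mers present in
its profile; the best reference's lineage is the point assignment (ties →
lowest record id, assignment backed off to the tied references' lowest
common rank).  Confidence at each rank is the fraction of `n_boot = 100`
bootstrap resamples (each `⌈m/8⌉` of the `m` distinct query k-mers, drawn
with replacement) whose best reference agrees with the point assignment at
that rank and all ranks above — so confidences are non-increasing from
kingdom to genus by construction.  Ranks are accepted down to the deepest
rank with confidence ≥ `conf_cutoff = 0.80`.

Species labels are governed by identity, not confidence: the centroid must
align to the best reference at ≥ 99% global identity (inclusive) with
≥ 90% query coverage, on top of a confident genus.  MOTU counts are then
tallied per sample at each MOTU's deepest accepted label into a
taxa × samples community matrix; unclassified MOTUs fall into an
`UNASSIGNED` row (reported, never verified), and samples with no reads are
flagged `NO_MOTU` and excluded from verification with an explicit
exclusion record.

### 2.5 Verification and summaries

A taxon is **detected** in a sample at a rank when the matrix rows
resolving to it sum to ≥ `min_reads = 5` reads.  Declared binomials are
projected to the requested rank through the reference taxonomy; declared
names missing from it count as not identified (with a warning).  The
printed percentage convention is followed exactly: absolute
%identified = identified/listed × 100 and relative %not-identified =
(listed − identified)/listed × 100, each rounded half-up to two decimals
(`decimal.Decimal`, `ROUND_HALF_UP`).  Because the two terms are rounded
independently, they sum to 100.00 except when the exact value lands on a
half-cent tie, in which case both round up and the sum is 100.01 (e.g.
1 of 32 → 3.13 + 96.88); the test suite checks this exhaustively.  Group
summaries (by product source, dosage form or locus) recompute percentages
from the summed counts, never from averaged per-sample percentages.

### 2.6 Ordination

Rows with total count < 10 across samples (putative contamination or
chimeras) are removed; counts get a pseudocount of 1 and are centred
log-ratio transformed per sample; PCA is computed from the eigen-
decomposition of the taxon covariance, each axis oriented so its largest-
magnitude loading is positive.  Euclidean distance in full CLR/PCA space
is the Aitchison distance.

## 3. The synthetic-data generator

Everything upstream of the FASTQ files is simulated, so the pipeline can
be validated against exact ground truth on a desk-scale machine.

* **Reference database** — per family, a random root sequence per locus
  (400–480 nt); genera mutate the root at 8% per site, species mutate the
  genus sequence at 4%.  Congeneric species therefore sit ~8% apart —
  comfortably below the 99% species-acceptance band, so the species rule
  is exercised rather than trivially satisfied.  Fungal contaminant
  references carry a non-plant kingdom so reports can flag them.
* **Formulations** — declared lists are drawn from the plant pool; each
  declared species drops out with probability 0.2 (processing
  degradation); undeclared admixture is added at rate 0.15 per declared
  species; fungal contamination occurs with probability 0.3 (1–2 taxa).
  Abundances over the present taxa are symmetric-Dirichlet(1)
  (`alpha=None` → exactly uniform).
* **Reads** — 300-nt pairs; per-base substitution probability ramps
  linearly from 5 × 10⁻⁴ at the read start to 5 × 10⁻³ at the end, and
  Phred scores encode the *true* rates (capped Q40), so the expected-error
  filter sees honest qualities.  1% of reads are chimeras spliced from two
  parent amplicons at a uniform breakpoint.  Read-level provenance is
  retained in a truth manifest.
* **Panel** — `default_scenario()` mirrors the audited study's shape:
  39 products (24 in-house powders; 15 registered products comprising
  1 powder, 9 capsules, 5 tablets) declaring 1–55 species, with depth
  scaling as 40 reads per declared species (minimum 200).

All randomness flows through seeded `numpy` generators: one master seed
spawns the database, formulation and read streams, and the pipeline drives
per-MOTU classification seeds from its own config seed.  Identical seeds
give byte-identical FASTQ and report files.

These are generator defaults, not claims about any real product line; the
generator's scope is to exercise every code path (dropout, admixture,
contamination, chimeras, errors, empty samples) at sizes that run in
seconds to minutes.

## 4. Numerical and determinism conventions

* Percentages: `Decimal` half-up at two decimals; group percentages from
  summed counts.
* Alignment: integer DP scores; banded path verified against the full DP
  by construction (band doubling until score stabilization) and by test
  oracles.
* All orderings are total: uniques by (−size, sequence), MOTUs by
  (−total size, centroid), references by record id, samples
  lexicographically — no dict-order or hash dependence.
* Classification is a pure function of
  (sequence, index, n_boot, conf_cutoff, rng_seed).

## 5. Validation

The test suite (pytest + derandomized hypothesis) checks each stage
against independent oracles: a pure-python Needleman–Wunsch, a brute-force
greedy clusterer, an independent re-implementation of the bootstrap RNG
protocol, Fraction-based percentage arithmetic and an SVD-based PCA.
Acceptance tests verify (i) exact reproduction of the published per-sample
and group-level family-verification results from the packaged counts, and
(ii) on synthetic data: 100% identification and authenticity on a
noise-free panel, ground-truth recovery across 20 seeded noisy scenarios
(every well-supported taxon detected, no phantom species), and read-count
conservation through every stage.

## 6. Limitations

* The generator uses substitution-only errors (no indels), uniform base
  composition and locus-independent divergence; real markers have indel
  variation, conserved cores and taxon-specific rates.
* One reference record per species per locus; real databases carry
  intraspecific variation and gaps in coverage, which shift both
  identification and misassignment rates.
* The classifier is presence/absence on k-mers (no k-mer weighting), and
  chimera handling is implicit (low-count filtering and the UNASSIGNED
  row) rather than an explicit detector.
* Verification treats the reference taxonomy as authoritative; declared
  names absent from it are counted as not identified rather than resolved
  against an external synonym service (a user-supplied synonym map is
  supported).
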