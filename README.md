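# herbmark

DNA-metabarcoding label verification for multi-ingredient herbal products.

Polyherbal medicines — powders, capsules, tablets blending anywhere from one
to dozens of plant ingredients — are routinely sold with ingredient lists
that sequencing cannot confirm.  DNA metabarcoding audits them: amplify one
or more barcode loci (an ITS2-like nuclear marker and an rbcL-like plastid
marker) from the product, sequence the amplicon pool, and compare the taxa
detected against the taxa declared on the label.  `herbmark` implements that
audit as a library:

* **Pre-processing** — paired-read merging with quality-aware consensus,
  expected-error filtering, dereplication.
* **MOTU clustering** — greedy centroid clustering of unique sequences at
  99% global identity (Needleman–Wunsch, end gaps penalized).
* **Taxonomic assignment** — a UTAX/RDP-style shared-k-mer classifier with
  bootstrap confidence per rank; species labels additionally require ≥ 99%
  global identity and ≥ 90% query coverage against the best reference.
* **Label verification** — at species, genus and family rank, declared taxa
  split into *identified* and *not identified*, detections absent from the
  label become *other detected*; percentages follow the published
  convention (half-up, two decimals); group summaries recompute percentages
  from summed counts; a product is flagged *authentic* when 100% of its
  listed taxa are identified at both family and genus rank.
* **Ordination** — low-count filtering, centred log-ratio transform and PCA
  (Aitchison geometry) of the taxa × samples community matrix.
* **Synthetic data** — a generator standing in for the sequencing run:
  hierarchically diverged reference databases, formulations with processing
  dropout, undeclared admixture and fungal contamination, error-ramped
  paired reads with true-rate Phred scores and spliced chimeras.  Ground
  truth is retained, so the whole chain can be validated exactly.

The package also ships the per-sample family-level verification counts of a
published 33-product audit of Thai herbal medicines, so the count-level part
of the analysis reproduces the published tables without any sequence data.

## A worked example

Reproduce the published group-level tables from the packaged counts
(`python examples/02_verify_from_counts.py`):

```
by product source:
locus source_type  n_listed  n_identified  n_not_identified  pct_identified_absolute  pct_not_identified_relative
 ITS2    IN_HOUSE       278           168               110                    60.43                        39.57
 ITS2  REGISTERED        59            42                17                    71.19                        28.81
 RBCL    IN_HOUSE       278           198                80                    71.22                        28.78
 RBCL  REGISTERED        59            45                14                    76.27                        23.73

totals per locus:
locus  n_listed  n_identified  n_not_identified  pct_identified_absolute  pct_not_identified_relative
 ITS2       337           210               127                    62.31                        37.69
 RBCL       337           243                94                    72.11                        27.89
```

Run a synthetic study end to end (`python examples/01_full_study.py`
simulates six products with realistic dropout, admixture, contamination,
sequencing errors and chimeras, then analyses them from FASTQ):

```
family-rank verification:
sample_id   rank  n_listed  n_identified  pct_identified_absolute other_detected_taxa
      S29 family        14            12                    85.71
      S30 family         4             2                    50.00              Iaceae
      S31 family         4             3                    75.00              Gaceae
      S32 family         1             1                   100.00          Fungaaceae
      S33 family         1             1                   100.00
      S34 family         4             3                    75.00   Fungcaceae;Gaceae

authenticity flags:
sample_id locus  authentic
      S29  ITS2      False
      ...
      S32  ITS2       True
```

Ingredients dropped during simulated processing come back *not identified*,
admixed plants appear under *other detected*, and fungal contaminants are
reported with their non-plant lineage.  See also
`examples/03_classify_sequence.py` (the two-part assignment rule on a single
query) and `examples/04_ordination.py` (Aitchison PCA of communities).

The same workflow is available from the command line:

```
herbmark simulate --seed 42 --out study/
herbmark run --config config.yaml --locus its2
herbmark verify-counts --out reports/          # packaged published counts
herbmark ordinate --matrix matrix_ITS2.tsv --out ord/ --plot
```

## Layout

```
src/herbmark/        library (taxonomy, alignment, preprocess, classify,
                     motu, verify, ordination, simulate, pipeline, cli)
src/herbmark/data/   packaged published per-sample verification counts
examples/            narrative walkthroughs of the main workflows
tests/               unit, property and acceptance tests (+ test oracles)
scripts/             acceptance report generator
docs/methods.md      model, algorithms, parameter rationale, limitations
```
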