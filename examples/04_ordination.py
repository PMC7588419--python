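"""Compositional ordination of sample communities.

Count data from metabarcoding are compositional: only relative abundances
carry information.  This example builds a taxa x samples matrix from a
simulated study, removes low-count rows, applies the centred log-ratio
transform and runs PCA, under which Euclidean distance between samples is
the Aitchison distance.

Run with:  python examples/04_ordination.py [out.png]
"""
from __future__ import annotations

import sys

import numpy as np

import herbmark as hm
from herbmark.simulate import ProductSpec, Scenario, simulate_study

products = tuple(
    ProductSpec(f"S{i + 1:02d}", n, "IN_HOUSE", "POWDER", 600)
    for i, n in enumerate((5, 5, 8, 8, 3, 3))
)
scenario = Scenario(products=products, loci=("ITS2",), n_families=6,
                    genera_per_family=2, species_per_genus=2, n_fungi=2)
bundle = simulate_study(scenario, seed=3)

# run the stages up to the community matrix
per_sample = {}
for label in bundle.labels:
    pairs = bundle.reads[(label.sample_id, "ITS2")]
    merged = [m for m in (hm.merge_pair(p) for p in pairs) if m is not None]
    kept, _ = hm.quality_filter(merged)
    per_sample[label.sample_id] = hm.dereplicate(kept)
motus = hm.cluster_motus(hm.pool_sample_uniques(per_sample))
index = hm.build_reference_index(
    [r for r in bundle.records if r.locus == "ITS2"], k=8
)
rng = np.random.default_rng(0)
classifications = {
    m.motu_id: hm.classify_sequence(
        m.centroid, index, rng_seed=int(rng.integers(2**31 - 1)),
        query_id=m.motu_id,
    )
    for m in motus
}
matrix = hm.tally_assignments(motus, classifications, list(per_sample))
print(f"community matrix: {matrix.counts.shape[0]} taxa x "
      f"{matrix.counts.shape[1]} samples")

# low-count filter, CLR, PCA
result = hm.ordinate(matrix.counts, min_total=10)
print("\nPC variance fractions:",
      np.round(result.variance_fractions[:4], 3))
print("\nsample scores (first two axes):")
print(result.scores.iloc[:, :2].round(3).to_string())

print("\nAitchison distances:")
d = hm.aitchison_distances(hm.filter_low_count(matrix.counts, 10))
print(d.round(2).to_string())

if len(sys.argv) > 1:
    from herbmark.ordination import plot_scores

    plot_scores(result, sys.argv[1])
    print(f"\nscatter written to {sys.argv[1]}")
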