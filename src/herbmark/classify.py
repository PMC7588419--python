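"""Per-rank taxonomic assignment with bootstrap confidence.

A UTAX/RDP-style shared-k-mer classifier: each reference is scored by the
number of distinct query k-mers present in its k-mer profile; the
best-scoring reference's lineage is the point assignment (ties broken by
lowest record id, with the assignment backed off to the tied references'
lowest common rank).  Confidence at each rank is the fraction of bootstrap
resamples (``n_boot`` draws of ceil(m/8) of the m query k-mers, with
replacement) whose best reference agrees with the point assignment at that
rank and at every rank above it, which makes confidences non-increasing
from kingdom to genus by construction.

Species-level labels are not governed by confidence but by the identity
rule: the query must align to the best reference at >= 99% global identity
(inclusive) with >= 90% query coverage.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import align_stats
from .taxonomy import RANKS, UNKNOWN, ReferenceIndex, kmer_profile

#: Ranks assigned by the bootstrap classifier (species is identity-governed).
CONF_RANKS = RANKS[:-1]

DEFAULT_N_BOOT = 100
DEFAULT_CONF_CUTOFF = 0.80
SPECIES_IDENTITY_THRESHOLD = 0.99
SPECIES_COVERAGE_THRESHOLD = 0.90


@dataclass(frozen=True)
class Classification:
    """Result of classifying one query sequence."""

    query_id: str
    labels: dict[str, str] = field(default_factory=dict)  # rank -> label
    confidences: dict[str, float] = field(default_factory=dict)
    species_label: str = UNKNOWN
    species_identity: float = 0.0
    species_coverage: float = 0.0
    accepted_rank: str | None = None
    best_record_id: str | None = None

    @property
    def is_classified(self) -> bool:
        return self.accepted_rank is not None

    def label_path(self) -> str:
        """Semicolon path down to the accepted rank (UNASSIGNED if none)."""
        if self.accepted_rank is None:
            return "UNASSIGNED"
        cut = RANKS.index(self.accepted_rank)
        labels = [self.labels.get(r, UNKNOWN) for r in CONF_RANKS] + [self.species_label]
        return ";".join(labels[: cut + 1])


def _unclassified(query_id: str) -> Classification:
    return Classification(
        query_id=query_id,
        labels={r: UNKNOWN for r in CONF_RANKS},
        confidences={r: 0.0 for r in CONF_RANKS},
    )


def _common_lineage(labels_list: list[tuple[str, ...]]) -> list[str]:
    """Labels agreed on by all lineages, top-down; UNKNOWN below the first
    disagreement."""
    out: list[str] = []
    disagree = False
    for i in range(len(RANKS)):
        vals = {labs[i] for labs in labels_list}
        if disagree or len(vals) != 1:
            disagree = True
            out.append(UNKNOWN)
        else:
            out.append(vals.pop())
    return out


def accept_species(
    query: str,
    best_ref_seq: str,
    threshold: float = SPECIES_IDENTITY_THRESHOLD,
    min_coverage: float = SPECIES_COVERAGE_THRESHOLD,
) -> bool:
    """Species-level acceptance: identity >= threshold (inclusive) and query
    coverage >= min_coverage."""
    stats = align_stats(query, best_ref_seq)
    return stats.identity >= threshold and stats.query_coverage >= min_coverage


def classify_sequence(
    seq: str,
    index: ReferenceIndex,
    n_boot: int = DEFAULT_N_BOOT,
    conf_cutoff: float = DEFAULT_CONF_CUTOFF,
    rng_seed: int = 0,
    query_id: str = "",
    species_threshold: float = SPECIES_IDENTITY_THRESHOLD,
    species_min_coverage: float = SPECIES_COVERAGE_THRESHOLD,
) -> Classification:
    """Classify one sequence against the reference index.

    Pure function of (seq, index, n_boot, conf_cutoff, rng_seed).  A query
    with zero valid k-mers is returned UNCLASSIFIED (all ranks UNKNOWN,
    confidence 0).
    """
    if not index.profiles:
        raise ValueError("reference index is empty")
    kmers = sorted(kmer_profile(seq, index.k))
    m = len(kmers)
    if m == 0:
        return _unclassified(query_id)
    ref_ids = index.record_ids  # sorted, so argmax ties pick the lowest id
    # membership matrix: query k-mer x reference
    member = np.zeros((m, len(ref_ids)), dtype=np.int64)
    for i, kmer in enumerate(kmers):
        for j, rid in enumerate(ref_ids):
            if kmer in index.profiles[rid]:
                member[i, j] = 1
    point_scores = member.sum(axis=0)
    top = int(point_scores.max())
    tied = [ref_ids[j] for j in np.flatnonzero(point_scores == top)]
    best_record_id = tied[0]
    point_labels = _common_lineage([index.lineages[rid].labels for rid in tied])

    rng = np.random.default_rng(rng_seed)
    subsample = math.ceil(m / 8)
    agree = np.zeros(len(CONF_RANKS), dtype=np.int64)
    tied_labels = {rid: index.lineages[rid].labels for rid in ref_ids}
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=subsample)
        scores = member[idx].sum(axis=0)
        boot_ref = ref_ids[int(np.argmax(scores))]
        boot_labels = tied_labels[boot_ref]
        for r in range(len(CONF_RANKS)):
            if point_labels[r] == UNKNOWN or boot_labels[r] != point_labels[r]:
                break
            agree[r] += 1
    confidences = {rank: float(agree[i]) / n_boot for i, rank in enumerate(CONF_RANKS)}
    labels = {rank: point_labels[i] for i, rank in enumerate(CONF_RANKS)}

    accepted_rank = None
    for i, rank in enumerate(CONF_RANKS):
        if labels[rank] != UNKNOWN and confidences[rank] >= conf_cutoff:
            accepted_rank = rank
        else:
            break

    stats = align_stats(seq, index.sequences[best_record_id])
    species_label = UNKNOWN
    point_species = point_labels[RANKS.index("species")]
    if (
        point_species != UNKNOWN
        and stats.identity >= species_threshold
        and stats.query_coverage >= species_min_coverage
        and accepted_rank == "genus"
    ):
        species_label = point_species
        accepted_rank = "species"

    return Classification(
        query_id=query_id,
        labels=labels,
        confidences=confidences,
        species_label=species_label,
        species_identity=float(stats.identity),
        species_coverage=float(stats.query_coverage),
        accepted_rank=accepted_rank,
        best_record_id=best_record_id,
    )
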