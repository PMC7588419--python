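"""MOTU clustering at 99% identity and community-matrix construction.

Greedy centroid clustering: unique sequences are processed in decreasing
abundance (ties broken lexicographically by sequence); each joins the first
existing centroid, in founding order, with global identity >= the threshold,
otherwise it founds a new MOTU.  MOTU read counts are then tallied per
sample at each MOTU's deepest accepted taxonomic label into a taxa x samples
community matrix with a lineage sidecar.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .alignment import global_identity
from .classify import Classification
from .preprocess import UniqueSeq
from .taxonomy import RANKS, UNKNOWN, Lineage

log = logging.getLogger(__name__)

MOTU_IDENTITY_THRESHOLD = 0.99
DEFAULT_MIN_READS = 5

#: Community-matrix row for reads whose MOTU consensus is unclassified.
UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class PooledUnique:
    """A unique sequence pooled across samples, with per-sample counts."""

    sequence: str
    size: int
    sample_counts: Mapping[str, int]


def pool_sample_uniques(
    per_sample: Mapping[str, Sequence[UniqueSeq]],
) -> list[PooledUnique]:
    """Aggregate per-sample dereplicated sequences across samples."""
    counts: dict[str, dict[str, int]] = defaultdict(dict)
    for sample_id, uniques in per_sample.items():
        for u in uniques:
            counts[u.sequence][sample_id] = counts[u.sequence].get(sample_id, 0) + u.size
    pooled = [
        PooledUnique(seq, sum(by_sample.values()), dict(sorted(by_sample.items())))
        for seq, by_sample in counts.items()
    ]
    pooled.sort(key=lambda p: (-p.size, p.sequence))
    return pooled


@dataclass
class MOTU:
    """A molecular operational taxonomic unit."""

    motu_id: str
    centroid: str
    members: list[PooledUnique] = field(default_factory=list)

    @property
    def total_size(self) -> int:
        return sum(m.size for m in self.members)

    @property
    def sample_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.members:
            for sample_id, n in m.sample_counts.items():
                out[sample_id] = out.get(sample_id, 0) + n
        return out


def cluster_motus(
    unique_seqs: Sequence[PooledUnique],
    threshold: float = MOTU_IDENTITY_THRESHOLD,
    identity_fn: Callable[[str, str], float] = global_identity,
) -> list[MOTU]:
    """Greedy centroid clustering; deterministic, ordered by total size
    descending (ties by centroid sequence)."""
    ordered = sorted(unique_seqs, key=lambda u: (-u.size, u.sequence))
    motus: list[MOTU] = []
    for u in ordered:
        for motu in motus:
            if identity_fn(u.sequence, motu.centroid) >= threshold:
                motu.members.append(u)
                break
        else:
            motus.append(MOTU(motu_id="", centroid=u.sequence, members=[u]))
    motus.sort(key=lambda mo: (-mo.total_size, mo.centroid))
    width = max(4, len(str(len(motus))))
    for i, motu in enumerate(motus, start=1):
        motu.motu_id = f"M{i:0{width}d}"
    return motus


@dataclass
class CommunityMatrix:
    """Taxa x samples read counts, with a lineage sidecar.

    Rows are keyed by the semicolon lineage path down to each MOTU's
    accepted rank; ``no_motu`` flags samples whose column is all zeros.
    """

    counts: pd.DataFrame
    lineages: dict[str, Lineage]
    no_motu: frozenset[str] = frozenset()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, matrix_path: str | Path, lineage_path: str | Path) -> None:
        self.counts.to_csv(matrix_path, sep="\t", index_label="taxon")
        with Path(lineage_path).open("w") as fh:
            fh.write("taxon\tlineage\n")
            for taxon in self.counts.index:
                lin = self.lineages.get(taxon)
                fh.write(f"{taxon}\t{lin.path() if lin else UNASSIGNED}\n")


def tally_assignments(
    motus: Sequence[MOTU],
    classifications: Mapping[str, Classification],
    samples: Sequence[str],
) -> CommunityMatrix:
    """Aggregate MOTU counts to their deepest accepted labels.

    Each MOTU's consensus classification is its centroid's; MOTUs with an
    unclassified consensus are tallied to an UNASSIGNED row (reported but
    excluded from verification).  Samples with no reads keep a column of
    zeros and are flagged NO_MOTU.
    """
    samples = sorted(samples)
    rows: dict[str, dict[str, int]] = {}
    lineages: dict[str, Lineage] = {}
    for motu in motus:
        cls = classifications[motu.motu_id]
        key = cls.label_path()
        if cls.accepted_rank is not None and key not in lineages:
            labels = [cls.labels.get(r, UNKNOWN) for r in RANKS[:-1]]
            labels.append(cls.species_label)
            lineages[key] = Lineage(*labels).truncate(cls.accepted_rank)
        row = rows.setdefault(key, {})
        for sample_id, n in motu.sample_counts.items():
            row[sample_id] = row.get(sample_id, 0) + n
    counts = pd.DataFrame(
        {s: {taxon: rows[taxon].get(s, 0) for taxon in rows} for s in samples},
        dtype=int,
    )
    counts = counts.reindex(sorted(rows), columns=samples).fillna(0).astype(int)
    no_motu = frozenset(s for s in samples if counts.empty or counts[s].sum() == 0)
    for s in sorted(no_motu):
        log.warning("sample %s yielded no MOTUs (NO_MOTU)", s)
    return CommunityMatrix(counts=counts, lineages=lineages, no_motu=no_motu)


def detected_taxa(
    matrix: CommunityMatrix,
    sample_id: str,
    rank: str,
    min_reads: int = DEFAULT_MIN_READS,
) -> set[str]:
    """Names at *rank* whose summed counts in *sample_id* reach min_reads.

    UNKNOWN labels (rows not resolved to the requested rank) and the
    UNASSIGNED row are excluded.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if sample_id not in matrix.counts.columns:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    totals: dict[str, int] = {}
    col = matrix.counts[sample_id]
    for taxon, count in col.items():
        lin = matrix.lineages.get(taxon)
        if lin is None:
            continue  # UNASSIGNED
        name = lin.at(rank)
        if name == UNKNOWN:
            continue
        totals[name] = totals.get(name, 0) + int(count)
    return {name for name, total in totals.items() if total >= min_reads}
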