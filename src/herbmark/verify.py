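"""Label verification: detected taxa vs declared ingredients.

The core audit: at each rank (species/genus/family) the taxa detected by
metabarcoding in a sample are compared with the taxa declared on the
product's label.  Declared taxa split into *identified* (declared and
detected) and *not identified* (declared but not detected); detections
absent from the label are *other detected*.  Percentages follow the printed
convention: absolute % identified = identified / listed x 100 and relative
% not identified = (listed - identified) / listed x 100, each rounded
half-up to two decimals.  Group summaries recompute percentages from summed
counts, never from averaged per-sample percentages.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .labels import FormulationLabel
from .motu import DEFAULT_MIN_READS, CommunityMatrix, detected_taxa
from .taxonomy import UNKNOWN, Lineage

log = logging.getLogger(__name__)

VERIFICATION_RANKS = ("species", "genus", "family")


def percentages(n_identified: int, n_listed: int) -> tuple[float, float]:
    """(absolute % identified, relative % not identified), both over the
    listed count, rounded half-up to 2 decimals."""
    if n_listed < 1:
        raise ValueError("n_listed must be >= 1")
    if not 0 <= n_identified <= n_listed:
        raise ValueError("n_identified must be in [0, n_listed]")
    q = Decimal("0.01")
    p_abs = (Decimal(100 * n_identified) / Decimal(n_listed)).quantize(q, ROUND_HALF_UP)
    p_rel = (Decimal(100 * (n_listed - n_identified)) / Decimal(n_listed)).quantize(
        q, ROUND_HALF_UP
    )
    return float(p_abs), float(p_rel)


@dataclass(frozen=True)
class CategorizedTaxa:
    identified: frozenset[str]
    not_identified: frozenset[str]
    other_detected: frozenset[str]
    unresolvable: frozenset[str] = frozenset()


def project_label(
    label: FormulationLabel,
    rank: str,
    lineage_by_species: Mapping[str, Lineage],
) -> tuple[set[str], set[str]]:
    """Project declared binomials to *rank* via the reference taxonomy.

    Returns (projected names, unresolvable declared names).  A declared name
    missing from the reference taxonomy (or unresolved at the rank) is
    UNRESOLVABLE; it is counted as not identified, with a warning.
    """
    if rank not in VERIFICATION_RANKS:
        raise ValueError(f"rank must be one of {VERIFICATION_RANKS}")
    projected: set[str] = set()
    unresolvable: set[str] = set()
    for name in label.declared_species:
        lineage = lineage_by_species.get(name)
        target = lineage.at(rank) if lineage is not None else UNKNOWN
        if target == UNKNOWN:
            unresolvable.add(name)
        else:
            projected.add(target)
    if unresolvable:
        log.warning(
            "label %s: %d declared name(s) unresolvable at %s rank: %s",
            label.sample_id, len(unresolvable), rank, sorted(unresolvable),
        )
    return projected, unresolvable


def categorize(
    label: FormulationLabel,
    detected: set[str],
    rank: str,
    lineage_by_species: Mapping[str, Lineage],
) -> CategorizedTaxa:
    """Split taxa at *rank* into identified / not identified / other detected.

    The three sets are disjoint; identified + not_identified partition the
    projected label set (unresolvable declared names count as not
    identified, keeping their species-level names).
    """
    projected, unresolvable = project_label(label, rank, lineage_by_species)
    identified = projected & detected
    not_identified = (projected - detected) | unresolvable
    other = detected - projected
    return CategorizedTaxa(
        identified=frozenset(identified),
        not_identified=frozenset(not_identified),
        other_detected=frozenset(other),
        unresolvable=frozenset(unresolvable),
    )


@dataclass(frozen=True)
class VerificationRecord:
    """Per sample x locus x rank verification outcome."""

    sample_id: str
    locus: str
    rank: str
    n_listed: int
    identified_taxa: frozenset[str]
    not_identified_taxa: frozenset[str]
    other_detected_taxa: frozenset[str]
    pct_identified_absolute: float
    pct_not_identified_relative: float

    @property
    def n_identified(self) -> int:
        return len(self.identified_taxa)

    @property
    def n_not_identified(self) -> int:
        return len(self.not_identified_taxa)


def _record(label: FormulationLabel, locus: str, rank: str, cats: CategorizedTaxa) -> VerificationRecord:
    n_listed = len(cats.identified) + len(cats.not_identified)
    p_abs, p_rel = percentages(len(cats.identified), n_listed)
    return VerificationRecord(
        sample_id=label.sample_id,
        locus=locus,
        rank=rank,
        n_listed=n_listed,
        identified_taxa=cats.identified,
        not_identified_taxa=cats.not_identified,
        other_detected_taxa=cats.other_detected,
        pct_identified_absolute=p_abs,
        pct_not_identified_relative=p_rel,
    )


def verify_sample(
    label: FormulationLabel,
    matrix: CommunityMatrix,
    locus: str,
    lineage_by_species: Mapping[str, Lineage],
    ranks: Sequence[str] = VERIFICATION_RANKS,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[VerificationRecord]:
    """One record per rank; a NO_MOTU sample yields no records (logged)."""
    if label.sample_id in matrix.no_motu:
        log.info("sample %s excluded from verification: NO_MOTU", label.sample_id)
        return []
    records = []
    for rank in ranks:
        detected = detected_taxa(matrix, label.sample_id, rank, min_reads=min_reads)
        cats = categorize(label, detected, rank, lineage_by_species)
        records.append(_record(label, locus, rank, cats))
    return records


@dataclass(frozen=True)
class GroupSummary:
    """Aggregated verification counts for one group (Table-3 style)."""

    group_by: str
    group: str
    locus: str
    rank: str
    n_samples: int
    n_listed: int
    n_identified: int
    n_not_identified: int
    pct_identified_absolute: float
    pct_not_identified_relative: float


def summarize(
    records: Sequence[VerificationRecord],
    labels_by_sample: Mapping[str, FormulationLabel],
    group_by: str,
) -> list[GroupSummary]:
    """Aggregate records (of a single rank) by source_type, dosage_form or
    locus; percentages are recomputed from the summed counts."""
    if not records:
        return []
    ranks = {r.rank for r in records}
    if len(ranks) != 1:
        raise ValueError(f"summarize needs a single rank, got {sorted(ranks)}")
    rank = ranks.pop()
    groups: dict[tuple[str, str], list[VerificationRecord]] = {}
    for rec in records:
        if group_by == "locus":
            key = (rec.locus, rec.locus)
        elif group_by in ("source_type", "dosage_form"):
            key = (getattr(labels_by_sample[rec.sample_id], group_by), rec.locus)
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        groups.setdefault(key, []).append(rec)
    out = []
    for (group, locus), members in sorted(groups.items()):
        n_listed = sum(r.n_listed for r in members)
        n_identified = sum(r.n_identified for r in members)
        p_abs, p_rel = percentages(n_identified, n_listed)
        out.append(
            GroupSummary(
                group_by=group_by,
                group=group,
                locus=locus,
                rank=rank,
                n_samples=len(members),
                n_listed=n_listed,
                n_identified=n_identified,
                n_not_identified=n_listed - n_identified,
                pct_identified_absolute=p_abs,
                pct_not_identified_relative=p_rel,
            )
        )
    return out


def authenticity_flag(records: Sequence[VerificationRecord]) -> bool:
    """A sample is authentic when 100% of its listed taxa are identified at
    both the family and genus ranks."""
    by_rank = {r.rank: r for r in records}
    for rank in ("family", "genus"):
        if rank not in by_rank:
            raise ValueError(f"authenticity needs a {rank}-rank record")
    return all(
        len(by_rank[rank].not_identified_taxa) == 0 for rank in ("family", "genus")
    )


# ---------------------------------------------------------------------------
# Verification directly from printed per-sample counts (bypasses sequencing).

def report_from_counts(counts: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Rebuild the per-sample and per-group family-verification reports from
    a table of per-sample listed/identified counts.

    *counts* needs columns sample_id, dosage_form, source_type, locus,
    n_listed, n_identified (one row per sample x locus).  Returns
    ``per_sample`` (with both percentages), ``by_source``, ``by_dosage`` and
    ``totals`` frames whose percentages are recomputed from summed counts.
    """
    required = {"sample_id", "dosage_form", "source_type", "locus", "n_listed", "n_identified"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    per_sample = counts.copy()
    pcts = [
        percentages(int(r.n_identified), int(r.n_listed))
        for r in per_sample.itertuples()
    ]
    per_sample["n_not_identified"] = per_sample["n_listed"] - per_sample["n_identified"]
    per_sample["pct_identified_absolute"] = [p[0] for p in pcts]
    per_sample["pct_not_identified_relative"] = [p[1] for p in pcts]

    def _group(frame: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        g = (
            frame.groupby(keys, as_index=False)[["n_listed", "n_identified"]]
            .sum()
            .sort_values(keys)
            .reset_index(drop=True)
        )
        gp = [percentages(int(r.n_identified), int(r.n_listed)) for r in g.itertuples()]
        g["n_not_identified"] = g["n_listed"] - g["n_identified"]
        g["pct_identified_absolute"] = [p[0] for p in gp]
        g["pct_not_identified_relative"] = [p[1] for p in gp]
        return g

    return {
        "per_sample": per_sample,
        "by_source": _group(per_sample, ["locus", "source_type"]),
        "by_dosage": _group(per_sample, ["locus", "dosage_form"]),
        "totals": _group(per_sample, ["locus"]),
    }
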