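"""Reference marker database: lineages, botanical name normalization, k-mer indexing.

The reference database is a plain FASTA of marker sequences (ITS2-like and
rbcL-like loci) plus a taxonomy TSV mapping each record to a seven-rank
lineage (kingdom;phylum;class;order;family;genus;species).  The index built
here backs the k-mer naive-Bayes-style classifier in :mod:`herbmark.classify`.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Rank names, shallow to deep, as used throughout the package.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Attribute names on :class:`Lineage` for each rank ("class" is reserved).
_RANK_ATTRS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")

#: Sentinel for an unresolved rank.
UNKNOWN = "UNKNOWN"

VALID_LOCI = ("ITS2", "RBCL")

_DNA_RE = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class Lineage:
    """A seven-rank taxonomic path, filled top-down.

    Invariants (enforced by :meth:`from_fields`):

    * once a rank is UNKNOWN every deeper rank is UNKNOWN;
    * a known species is a two-token binomial whose first token is the genus.
    """

    kingdom: str = UNKNOWN
    phylum: str = UNKNOWN
    class_: str = UNKNOWN
    order: str = UNKNOWN
    family: str = UNKNOWN
    genus: str = UNKNOWN
    species: str = UNKNOWN

    def at(self, rank: str) -> str:
        """Label at *rank* (one of :data:`RANKS`)."""
        return getattr(self, _RANK_ATTRS[RANKS.index(rank)])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(getattr(self, a) for a in _RANK_ATTRS)

    @property
    def rank_resolution(self) -> str | None:
        """Deepest non-UNKNOWN rank, or None if fully unresolved."""
        deepest = None
        for rank, label in zip(RANKS, self.labels):
            if label == UNKNOWN:
                break
            deepest = rank
        return deepest

    def truncate(self, rank: str) -> "Lineage":
        """Copy with every rank deeper than *rank* set to UNKNOWN."""
        cut = RANKS.index(rank)
        labels = [lab if i <= cut else UNKNOWN for i, lab in enumerate(self.labels)]
        return Lineage(*labels)

    def path(self, rank: str | None = None) -> str:
        """Semicolon-joined labels down to *rank* (default: all seven)."""
        cut = len(RANKS) - 1 if rank is None else RANKS.index(rank)
        return ";".join(self.labels[: cut + 1])

    @classmethod
    def from_fields(cls, fields: Iterable[str], context: str = "") -> "Lineage":
        """Build a lineage from seven raw rank strings.

        Blank/NA fields become UNKNOWN; top-down fill and the binomial
        invariant are enforced by coercion, with a logged warning.
        """
        raw = [f.strip() for f in fields]
        if len(raw) != len(RANKS):
            raise ValueError(
                f"expected {len(RANKS)} rank fields, got {len(raw)}"
                + (f" ({context})" if context else "")
            )
        labels = [f if f and f.upper() not in ("NA", UNKNOWN) else UNKNOWN for f in raw]
        blanked = False
        for i, lab in enumerate(labels):
            if blanked and lab != UNKNOWN:
                log.warning(
                    "rank %s=%r below an unresolved rank coerced to UNKNOWN%s",
                    RANKS[i], lab, f" ({context})" if context else "",
                )
                labels[i] = UNKNOWN
            if labels[i] == UNKNOWN:
                blanked = True
        genus, species = labels[5], labels[6]
        if species != UNKNOWN:
            toks = species.split()
            if len(toks) != 2 or toks[0] != genus:
                log.warning(
                    "species %r inconsistent with genus %r, coerced to UNKNOWN%s",
                    species, genus, f" ({context})" if context else "",
                )
                labels[6] = UNKNOWN
        return cls(*labels)


def parse_taxonomy_table(path: str | Path) -> list[tuple[str, Lineage]]:
    """Parse a taxonomy TSV: ``record_id<TAB>kingdom;...;species`` per row.

    Raises ``ValueError`` on a duplicate record id (naming the id) or a
    malformed row (naming the line number).
    """
    path = Path(path)
    out: list[tuple[str, Lineage]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            record_id, lineage_str = parts
            if record_id in seen:
                raise ValueError(f"{path}: duplicate record_id {record_id!r}")
            seen.add(record_id)
            fields = lineage_str.split(";")
            try:
                lineage = Lineage.from_fields(fields, context=f"line {lineno}")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append((record_id, lineage))
    return out


def write_taxonomy_table(rows: Iterable[tuple[str, Lineage]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for record_id, lineage in rows:
            fh.write(f"{record_id}\t{lineage.path()}\n")


_BRACKETS_RE = re.compile(r"[(\[][^)\]]*[)\]]")
_INFRA_MARKERS = {"var.", "subsp.", "ssp.", "f.", "cv.", "subvar."}


def normalize_binomial(raw_name: str) -> str:
    """Canonicalize a botanical name to ``Genus epithet``.

    Author citations (e.g. "Roscoe", "(L.f.) Royle"), infraspecific markers
    (var., subsp., ...) and bracketed annotations are stripped; the genus is
    capitalized and the epithet lower-cased.  Idempotent.  A single-token
    input is returned as a genus-only marker, matchable at genus rank only.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("empty name")
    cleaned = _BRACKETS_RE.sub(" ", raw_name).replace("×", " ").strip()
    tokens = cleaned.split()
    if not tokens:
        raise ValueError(f"no name tokens in {raw_name!r}")
    genus = tokens[0].capitalize()
    if len(tokens) >= 2:
        epithet = tokens[1]
        # An epithet is purely alphabetic (hyphens allowed) and never an
        # infraspecific marker; author abbreviations carry dots or capitals.
        if (
            epithet.lower() not in _INFRA_MARKERS
            and epithet.replace("-", "").isalpha()
            and epithet == epithet.lower()
        ):
            return f"{genus} {epithet}"
    return genus


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Optional user-supplied synonym TSV: raw_name<TAB>canonical_name."""
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            raw, canonical = line.split("\t")
            out[normalize_binomial(raw)] = normalize_binomial(canonical)
    return out


@dataclass(frozen=True)
class RefRecord:
    """One reference marker sequence with its lineage."""

    record_id: str
    locus: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if self.locus not in VALID_LOCI:
            raise ValueError(f"unknown locus {self.locus!r} for {self.record_id}")
        if not _DNA_RE.match(self.sequence):
            raise ValueError(
                f"record {self.record_id}: sequence must be uppercase A/C/G/T/N"
            )


def load_reference(fasta_path: str | Path, taxonomy_path: str | Path) -> list[RefRecord]:
    """Read the reference FASTA + taxonomy TSV into validated records.

    FASTA descriptions must carry a ``locus=ITS2|RBCL`` tag.  Every record id
    must appear in the taxonomy table exactly once.
    """
    lineages = dict(parse_taxonomy_table(taxonomy_path))
    records: list[RefRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{fasta_path}: duplicate record_id {rec.id!r}")
        seen.add(rec.id)
        m = re.search(r"locus=(\S+)", rec.description)
        if not m:
            raise ValueError(f"{fasta_path}: record {rec.id} lacks a locus= tag")
        if rec.id not in lineages:
            raise ValueError(f"record {rec.id} missing from taxonomy table")
        records.append(
            RefRecord(rec.id, m.group(1).upper(), str(rec.seq).upper(), lineages[rec.id])
        )
    return records


def write_reference_fasta(records: Iterable[RefRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.record_id} locus={rec.locus}\n{rec.sequence}\n")


def kmer_profile(sequence: str, k: int) -> frozenset[str]:
    """Distinct k-mers of *sequence*; k-mers containing N (or any non-ACGT
    character) are skipped."""
    if k < 1:
        raise ValueError("k must be positive")
    seq = sequence.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if _DNA_RE.match(kmer) and "N" not in kmer:
            out.add(kmer)
    return frozenset(out)


@dataclass
class ReferenceIndex:
    """K-mer presence profiles plus per-rank membership maps.

    Every indexed record id resolves to exactly one lineage; sequences are
    retained so the classifier can compute the species-level global identity
    against the best-scoring reference.
    """

    k: int
    profiles: dict[str, frozenset[str]]
    sequences: dict[str, str]
    lineages: dict[str, Lineage]
    rank_members: dict[str, dict[str, frozenset[str]]]

    @property
    def record_ids(self) -> list[str]:
        return sorted(self.profiles)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "profiles": {rid: sorted(p) for rid, p in self.profiles.items()},
            "sequences": dict(self.sequences),
            "lineages": {rid: list(lin.labels) for rid, lin in self.lineages.items()},
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ReferenceIndex":
        lineages = {rid: Lineage(*labs) for rid, labs in payload["lineages"].items()}
        profiles = {rid: frozenset(p) for rid, p in payload["profiles"].items()}
        return cls(
            k=int(payload["k"]),
            profiles=profiles,
            sequences=dict(payload["sequences"]),
            lineages=lineages,
            rank_members=_rank_members(lineages),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceIndex":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _rank_members(lineages: Mapping[str, Lineage]) -> dict[str, dict[str, frozenset[str]]]:
    members: dict[str, dict[str, set[str]]] = {rank: {} for rank in RANKS}
    for rid, lineage in lineages.items():
        for rank in RANKS:
            label = lineage.at(rank)
            if label != UNKNOWN:
                members[rank].setdefault(label, set()).add(rid)
    return {
        rank: {name: frozenset(ids) for name, ids in by_name.items()}
        for rank, by_name in members.items()
    }


def build_reference_index(records: Iterable[RefRecord], k: int = 8) -> ReferenceIndex:
    """Index records for classification.

    Records shorter than *k* are excluded with a warning; duplicate record
    ids are a hard error.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    profiles: dict[str, frozenset[str]] = {}
    sequences: dict[str, str] = {}
    lineages: dict[str, Lineage] = {}
    for rec in records:
        if rec.record_id in profiles:
            raise ValueError(f"duplicate record_id {rec.record_id!r}")
        if len(rec.sequence) < k:
            log.warning("record %s shorter than k=%d, excluded", rec.record_id, k)
            continue
        profiles[rec.record_id] = kmer_profile(rec.sequence, k)
        sequences[rec.record_id] = rec.sequence
        lineages[rec.record_id] = rec.lineage
    return ReferenceIndex(
        k=k,
        profiles=profiles,
        sequences=sequences,
        lineages=lineages,
        rank_members=_rank_members(lineages),
    )


def species_lineage_map(records: Iterable[RefRecord]) -> dict[str, Lineage]:
    """Map each known species binomial to its lineage (first record wins;
    conflicting lineages for one binomial raise)."""
    out: dict[str, Lineage] = {}
    for rec in records:
        sp = rec.lineage.species
        if sp == UNKNOWN:
            continue
        if sp in out and out[sp] != rec.lineage:
            raise ValueError(f"conflicting lineages for species {sp!r}")
        out.setdefault(sp, rec.lineage)
    return out
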