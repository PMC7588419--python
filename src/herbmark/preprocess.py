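"""Paired-read merging, expected-error quality filtering, dereplication.

Mirrors the conventional amplicon pre-processing chain: the reverse read is
reverse-complemented and slid over the forward read; the overlap (>=
``min_overlap``) maximizing the number of matching bases wins (ties go to
the longer overlap); pairs whose best overlap exceeds the mismatch-fraction
cap are rejected.  Merged reads are then filtered on length and on the
expected-error statistic EE = sum(10^(-Q/10)) and collapsed to unique
sequences with multiplicities.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")

#: merge_pair() returns this (None) for an unmergeable pair; it is a value,
#: not an exception.
REJECT = None

PHRED_OFFSET = 33
MAX_QUAL = 41

TOO_SHORT = "TOO_SHORT"
TOO_LONG = "TOO_LONG"
HIGH_EE = "HIGH_EE"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    sequence: str
    qualities: str
    overlap_len: int
    mismatches_in_overlap: int


@dataclass(frozen=True)
class UniqueSeq:
    """A dereplicated sequence with its multiplicity."""

    sequence: str
    size: int
    member_read_ids: tuple[str, ...]


def _quals_to_ints(qualities: str) -> np.ndarray:
    arr = np.frombuffer(qualities.encode("ascii"), dtype=np.uint8).astype(np.int64)
    return arr - PHRED_OFFSET


def merge_pair(pair, min_overlap: int = 30, max_mismatch_frac: float = 0.1):
    """Merge a read pair, or return :data:`REJECT`.

    Both overlap layouts are scanned (forward read leftmost, and the
    reverse-complemented mate leftmost, which covers a swapped pair), so
    merging is symmetric under (fwd, rev) -> (revcomp(rev), revcomp(fwd)).
    Disagreeing overlap bases resolve to the higher-quality base with quality
    |q1-q2|; an equal-quality disagreement resolves to N (the only choice
    symmetric under swapping the reads), also with quality 0.  Agreeing bases
    get min(q1+q2, 41).
    """
    fwd, fq = pair.fwd_seq, pair.fwd_qual
    rc = revcomp(pair.rev_seq)
    rq = pair.rev_qual[::-1]
    if min(len(fwd), len(rc)) < min_overlap:
        return REJECT
    fa = np.frombuffer(fwd.encode("ascii"), dtype=np.uint8)
    ra = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
    best = None  # (matches, o, layout)
    for layout, (s1, s2) in enumerate(((fa, ra), (ra, fa))):
        n1 = s1.size
        for o in range(min(s1.size, s2.size), min_overlap - 1, -1):
            matches = int(np.count_nonzero(s1[n1 - o :] == s2[:o]))
            if best is None or matches > best[0]:
                best = (matches, o, layout)
    best_matches, o, layout = best
    mismatches = o - best_matches
    if mismatches / o > max_mismatch_frac:
        return REJECT
    if layout == 0:
        s1, q1, s2, q2 = fwd, fq, rc, rq
    else:
        s1, q1, s2, q2 = rc, rq, fwd, fq
    n1 = len(s1)
    over1, over2 = s1[n1 - o :], s2[:o]
    qi1 = _quals_to_ints(q1[n1 - o :])
    qi2 = _quals_to_ints(q2[:o])
    cons_bases: list[str] = []
    cons_quals: list[int] = []
    for i in range(o):
        if over1[i] == over2[i]:
            cons_bases.append(over1[i])
            cons_quals.append(min(int(qi1[i] + qi2[i]), MAX_QUAL))
        else:
            cons_quals.append(int(abs(qi1[i] - qi2[i])))
            if qi1[i] > qi2[i]:
                cons_bases.append(over1[i])
            elif qi2[i] > qi1[i]:
                cons_bases.append(over2[i])
            else:
                cons_bases.append("N")
    merged_seq = s1[: n1 - o] + "".join(cons_bases) + s2[o:]
    merged_qual = (
        q1[: n1 - o]
        + "".join(chr(q + PHRED_OFFSET) for q in cons_quals)
        + q2[o:]
    )
    return MergedRead(
        read_id=pair.read_id,
        sequence=merged_seq,
        qualities=merged_qual,
        overlap_len=o,
        mismatches_in_overlap=mismatches,
    )


def expected_errors(qualities: str) -> float:
    """EE = sum over bases of 10^(-Q/10), Q decoded from Phred+33."""
    if not qualities:
        raise ValueError("empty quality string")
    for pos, ch in enumerate(qualities):
        if not (PHRED_OFFSET <= ord(ch) <= 126):
            raise ValueError(f"invalid Phred+33 character {ch!r} at position {pos}")
    q = _quals_to_ints(qualities)
    return float(np.sum(10.0 ** (-q / 10.0)))


def quality_filter(
    reads: Iterable[MergedRead],
    max_ee: float = 1.0,
    min_len: int = 150,
    max_len: int = 600,
) -> tuple[list[MergedRead], list[tuple[MergedRead, str]]]:
    """Split reads into (kept, rejected-with-reason).

    A read is kept iff min_len <= len <= max_len and EE <= max_ee; rejection
    reasons are TOO_SHORT / TOO_LONG / HIGH_EE (checked in that order).
    """
    kept: list[MergedRead] = []
    rejected: list[tuple[MergedRead, str]] = []
    for read in reads:
        n = len(read.sequence)
        if n < min_len:
            rejected.append((read, TOO_SHORT))
        elif n > max_len:
            rejected.append((read, TOO_LONG))
        elif expected_errors(read.qualities) > max_ee:
            rejected.append((read, HIGH_EE))
        else:
            kept.append(read)
    return kept, rejected


def dereplicate(reads: Sequence[MergedRead]) -> list[UniqueSeq]:
    """Collapse identical sequences; sort by size descending, then sequence."""
    groups: dict[str, list[str]] = defaultdict(list)
    for read in reads:
        groups[read.sequence].append(read.read_id)
    uniques = [
        UniqueSeq(seq, len(ids), tuple(ids)) for seq, ids in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.size, u.sequence))
    return uniques


def write_derep_fasta(uniques: Iterable[UniqueSeq], path: str | Path) -> None:
    """Write dereplicated sequences with ``;size=N`` header annotations."""
    with Path(path).open("w") as fh:
        for i, u in enumerate(uniques, start=1):
            fh.write(f">U{i};size={u.size}\n{u.sequence}\n")
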