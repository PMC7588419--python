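"""Independent reference implementations ("oracles") used by the tests.

Each oracle re-derives a quantity the package computes, using a deliberately
different (simpler, slower) implementation path, so agreement is evidence of
correctness rather than of shared code.  Nothing here imports the modules it
checks except for shared *protocol* constants (scoring weights, rank names)
that define the problem itself.
"""
from __future__ import annotations

import math
from decimal import Decimal
from fractions import Fraction

import numpy as np

MATCH = 1
MISMATCH = -1
GAP = -2


def nw_full_dp(a: str, b: str) -> tuple[int, int, int, int]:
    """Pure-python full Needleman-Wunsch with end gaps penalized.

    Tie-break among equal-score traceback moves: diagonal, then up, then
    left.  Returns (score, matches, columns, aligned_both).
    """
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    P = [[0] * (m + 1) for _ in range(n + 1)]  # 1 diag, 2 up, 3 left
    for i in range(1, n + 1):
        S[i][0] = GAP * i
        P[i][0] = 2
    for j in range(1, m + 1):
        S[0][j] = GAP * j
        P[0][j] = 3
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = MATCH if ai == b[j - 1] else MISMATCH
            best, ptr = S[i - 1][j - 1] + sub, 1
            up = S[i - 1][j] + GAP
            if up > best:
                best, ptr = up, 2
            left = S[i][j - 1] + GAP
            if left > best:
                best, ptr = left, 3
            S[i][j] = best
            P[i][j] = ptr
    i, j = n, m
    matches = columns = aligned_both = 0
    while i > 0 or j > 0:
        ptr = P[i][j]
        columns += 1
        if ptr == 1:
            if a[i - 1] == b[j - 1]:
                matches += 1
            aligned_both += 1
            i -= 1
            j -= 1
        elif ptr == 2:
            i -= 1
        else:
            j -= 1
    return S[n][m], matches, columns, aligned_both


def identity_oracle(a: str, b: str) -> float:
    """Symmetric global identity: canonicalize the pair (shorter, then
    lexicographically smaller, first), then matches / columns."""
    if a == b:
        return 1.0
    if (len(b), b) < (len(a), a):
        a, b = b, a
    _, matches, columns, _ = nw_full_dp(a, b)
    return matches / columns


def greedy_cluster_oracle(
    sized_seqs: list[tuple[str, int]], threshold: float, identity_fn
) -> list[list[str]]:
    """Brute-force greedy centroid clustering.

    Input (sequence, size) pairs; processes in decreasing size (ties by
    sequence), joins the first centroid in founding order with identity >=
    threshold.  Returns member-sequence lists in founding order.
    """
    ordered = sorted(sized_seqs, key=lambda t: (-t[1], t[0]))
    clusters: list[list[str]] = []
    for seq, _ in ordered:
        for members in clusters:
            if identity_fn(seq, members[0]) >= threshold:
                members.append(seq)
                break
        else:
            clusters.append([seq])
    return clusters


def kmer_set(seq: str, k: int) -> set[str]:
    return {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if set(seq[i : i + k]) <= set("ACGT")
    }


def bootstrap_confidence_oracle(
    query: str,
    ref_seqs: dict[str, str],
    ref_lineages: dict[str, tuple[str, ...]],
    k: int,
    n_boot: int,
    rng_seed: int,
) -> tuple[str, list[str], dict[int, float]]:
    """Independent re-derivation of the bootstrap classifier protocol.

    Scores each reference by distinct shared query k-mers; ties pick the
    lowest record id and back the point lineage off to the tied references'
    common prefix.  Bootstrap: n_boot draws of ceil(m/8) indices into the
    sorted distinct query k-mers (with replacement, multiplicity kept) from
    np.random.default_rng(rng_seed); per-rank confidence is the fraction of
    draws agreeing with the point lineage at that rank and all ranks above.

    Returns (best_record_id, point_labels[7], {rank_index: confidence}) for
    the six supra-species ranks.
    """
    kmers = sorted(kmer_set(query, k))
    m = len(kmers)
    assert m > 0, "oracle expects a query with at least one valid k-mer"
    ref_ids = sorted(ref_seqs)
    profiles = {rid: kmer_set(ref_seqs[rid], k) for rid in ref_ids}
    point_scores = [sum(km in profiles[rid] for km in kmers) for rid in ref_ids]
    top = max(point_scores)
    tied = [rid for rid, s in zip(ref_ids, point_scores) if s == top]
    best = tied[0]
    point: list[str] = []
    disagree = False
    for r in range(7):
        vals = {ref_lineages[rid][r] for rid in tied}
        if disagree or len(vals) != 1:
            disagree = True
            point.append("UNKNOWN")
        else:
            point.append(vals.pop())
    rng = np.random.default_rng(rng_seed)
    sub = math.ceil(m / 8)
    agree = [0] * 6
    for _ in range(n_boot):
        idx = rng.integers(0, m, size=sub)
        drawn = [kmers[int(i)] for i in idx]
        scores = [sum(km in profiles[rid] for km in drawn) for rid in ref_ids]
        boot_ref = ref_ids[int(np.argmax(scores))]
        for r in range(6):
            if point[r] == "UNKNOWN" or ref_lineages[boot_ref][r] != point[r]:
                break
            agree[r] += 1
    return best, point, {r: agree[r] / n_boot for r in range(6)}


def percentages_oracle(n_identified: int, n_listed: int) -> tuple[str, str]:
    """Half-up 2-decimal percentages via Fraction arithmetic, formatted."""
    out = []
    for num in (100 * n_identified, 100 * (n_listed - n_identified)):
        frac = Fraction(num, n_listed)
        cents = frac * 100  # value in hundredths of a percent
        floor = cents.numerator // cents.denominator
        rem = cents - floor
        rounded = floor + (1 if rem >= Fraction(1, 2) else 0)
        out.append(f"{Decimal(rounded) / 100:.2f}")
    return out[0], out[1]


def percentage_sum_is_100_01(n_identified: int, n_listed: int) -> bool:
    """True iff the two half-up-rounded percentages sum to 100.01.

    This happens exactly when 10000 * a / n lands on a half-cent tie (both
    terms then round up); otherwise the sum is exactly 100.00.
    """
    cents = Fraction(10000 * n_identified, n_listed)
    frac = cents - (cents.numerator // cents.denominator)
    return frac == Fraction(1, 2)


def clr_oracle(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """CLR per column via explicit geometric mean."""
    x = counts.astype(float) + pseudocount
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        g = np.exp(np.mean(np.log(x[:, j])))
        out[:, j] = np.log(x[:, j] / g)
    return out


def pca_svd_oracle(clr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and variance fractions via SVD of centered samples x taxa.

    Applies the same sign convention as the package (largest-|loading|
    entry of each axis positive) so scores are directly comparable.
    """
    X = clr.T  # samples x taxa
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt.T
    n_taxa = clr.shape[0]
    if V.shape[1] < n_taxa:  # pad rank-deficient case to n_taxa axes
        pad = n_taxa - V.shape[1]
        V = np.hstack([V, np.zeros((V.shape[0], pad))])
        s = np.concatenate([s, np.zeros(pad)])
    for a in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, a])))
        if V[i, a] < 0:
            V[:, a] = -V[:, a]
    scores = Xc @ V
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    return scores, fractions


def expected_errors_oracle(qualities: str) -> float:
    return sum(10.0 ** (-(ord(c) - 33) / 10.0) for c in qualities)
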