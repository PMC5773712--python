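"""Independent brute-force oracles used by the test suite.

These expand the feature-component definition literally, term by term,
with their own pair-function evaluation and naive double-scan adjacency
counting -- sharing nothing with the package's encoder path except the
normalized property tables themselves.
"""

from __future__ import annotations

import math

ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
CROSS = {1: (1, 2), 2: (1, 3), 3: (2, 3)}


def theta_oracle(l: str, m: str, scheme_id: int, tables) -> float:
    """Literal evaluation of the pair function from the normalized tables."""
    ds = tables.normalized[scheme_id]
    first = math.sqrt(ds[l] ** 2 * abs(ds[l] - ds[m]) ** 2)
    a, b = CROSS[scheme_id]
    da, db = tables.normalized[a], tables.normalized[b]
    ma = sum(da[r] for r in ALPHABET) / 20.0
    mb = sum(db[r] for r in ALPHABET) / 20.0
    ssa = sum((da[r] - ma) ** 2 for r in ALPHABET)
    ssb = sum((db[r] - mb) ** 2 for r in ALPHABET)
    cross = abs((da[l] - ma) * (db[m] - mb)) / math.sqrt(ssa * ssb)
    return first + cross


def adjacency_oracle(sequence: str) -> dict:
    """Directed adjacency counts by naive double scan over all residue pairs."""
    counts = {}
    for l in ALPHABET:
        for m in ALPHABET:
            c = 0
            for t in range(len(sequence) - 1):
                if sequence[t] == l and sequence[t + 1] == m:
                    c += 1
            if c:
                counts[(l, m)] = c
    return counts


def xy_oracle(sequence: str, residue: str, scheme_id: int, tables) -> float:
    """The {X + Y} bracket: count-weighted directed neighbour sums over 38."""
    counts = adjacency_oracle(sequence)
    total = 0.0
    for k in ALPHABET:
        if k == residue:
            continue
        total += counts.get((k, residue), 0) * theta_oracle(k, residue, scheme_id, tables)
        total += counts.get((residue, k), 0) * theta_oracle(residue, k, scheme_id, tables)
    return total / 38.0


def pi_oracle_parts(sequence: str, residue: str, scheme_id: int, tables):
    """(core, leading, trailing) parts of the feature component, expanded literally."""
    positions = [t + 1 for t, c in enumerate(sequence) if c == residue]
    lam = len(positions)
    if lam == 0:
        return 0.0, 0.0, 0.0
    N = len(sequence)
    xy = xy_oracle(sequence, residue, scheme_id, tables)

    core = lam + math.factorial(lam - 1) * theta_oracle(residue, residue, scheme_id, tables)
    for t in range(lam - 1):
        core += (positions[t + 1] - positions[t]) * xy
    leading = positions[0] * xy if positions[0] > 1 else 0.0
    trailing = (N - positions[-1]) * xy if positions[-1] < N else 0.0
    return core, leading, trailing


def pi_oracle(sequence: str, residue: str, scheme_id: int, tables) -> float:
    core, leading, trailing = pi_oracle_parts(sequence, residue, scheme_id, tables)
    return core + leading + trailing


def auc_pairwise_oracle(scores, labels) -> float:
    """Probability of correct ranking over all positive/negative pairs (ties = 1/2)."""
    pos = [s for s, lab in zip(scores, labels) if lab == "secretory"]
    neg = [s for s, lab in zip(scores, labels) if lab == "non_secretory"]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
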