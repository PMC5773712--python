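"""Residue pair statistics: the pair function, adjacency counts and rho indicators.

The pair function theta(l, m) couples two residues through the normalized
property scales.  For scheme s in {1, 2, 3} it is

    theta(l, m) = sqrt( d*_s(l)^2 * |d*_s(l) - d*_s(m)|^2 )
                + |(d*_a(l) - mean_a) (d*_b(m) - mean_b)|
                  / sqrt( sum_l (d*_a(l) - mean_a)^2 * sum_m (d*_b(m) - mean_b)^2 )

where the cross pair (a, b) is (1,2), (1,3), (2,3) for schemes 1, 2, 3
(hydrophobicity=1, hydrophilicity=2, side-chain mass=3), the first-term
property s equals the scheme id, and the means/sums run over the 20-residue
alphabet.  Both terms are non-negative; theta is not symmetric in general.

Adjacency pair counts f record how often residue l immediately precedes m
in a sequence; the rho matrix is their 0/1 existence indicator.  The
directed, count-weighted sums over a residue's neighbours (normalized by
1/38 = 1/(2*19) directed pair classes) are the X/Y bracket reused by every
positional weight in the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .properties import ALPHABET, INDEX, N_RESIDUES, PROPERTY_IDS, PropertyTable

#: scheme id -> (a, b) property pair of the correlation term.
CROSS_PAIRS = {1: (1, 2), 2: (1, 3), 3: (2, 3)}

#: 2 * 19 directed pair classes around a residue.
PAIR_CLASS_NORM = 38.0


@dataclass(frozen=True)
class PairScheme:
    """One of the three property couplings used by the encoder."""

    scheme_id: int
    first_term_property: int
    cross_pair: tuple

    @classmethod
    def from_id(cls, scheme_id: int, first_term_property: int | None = None) -> "PairScheme":
        """Build the scheme; ``first_term_property`` defaults to the scheme id."""
        if scheme_id not in CROSS_PAIRS:
            raise ValueError(f"scheme_id must be 1, 2 or 3, got {scheme_id}")
        s = scheme_id if first_term_property is None else first_term_property
        if s not in PROPERTY_IDS:
            raise ValueError(f"first_term_property must be 1, 2 or 3, got {s}")
        return cls(scheme_id=scheme_id, first_term_property=s, cross_pair=CROSS_PAIRS[scheme_id])


SCHEMES = tuple(PairScheme.from_id(i) for i in (1, 2, 3))


@dataclass(frozen=True)
class PairCounts:
    """20x20 directed adjacency counts: counts[l, m] = #{t : seq[t]=l, seq[t+1]=m}."""

    counts: np.ndarray

    def __post_init__(self):
        if self.counts.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError("counts must be 20x20")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RhoMatrix:
    """0/1 pair-existence indicator derived from PairCounts."""

    rho: np.ndarray

    def lower(self) -> np.ndarray:
        """Strictly lower-triangular part (pairs counted toward X)."""
        return np.tril(self.rho, k=-1)

    def diagonal(self) -> np.ndarray:
        return np.diag(np.diag(self.rho))

    def upper(self) -> np.ndarray:
        """Strictly upper-triangular part (pairs counted toward Y)."""
        return np.triu(self.rho, k=1)


def theta(l: str, m: str, scheme: PairScheme, tables: PropertyTable) -> float:
    """Pair function between residues ``l`` and ``m`` under ``scheme``."""
    for res in (l, m):
        if res not in INDEX:
            raise ValueError(f"unknown residue: {res!r}")
    s = scheme.first_term_property
    ds = tables.normalized[s]
    first = np.sqrt(ds[l] ** 2 * abs(ds[l] - ds[m]) ** 2)

    a, b = scheme.cross_pair
    da, db = tables.normalized[a], tables.normalized[b]
    ma, mb = tables.means[a], tables.means[b]
    ssa = sum((da[r] - ma) ** 2 for r in ALPHABET)
    ssb = sum((db[r] - mb) ** 2 for r in ALPHABET)
    cross = abs((da[l] - ma) * (db[m] - mb)) / np.sqrt(ssa * ssb)
    return float(first + cross)


def theta_matrix(scheme: PairScheme, tables: PropertyTable) -> np.ndarray:
    """20x20 matrix T with T[l, m] = theta(l, m); vectorized over the alphabet."""
    ds = tables.norm_array(scheme.first_term_property)
    first = np.sqrt(ds[:, None] ** 2 * np.abs(ds[:, None] - ds[None, :]) ** 2)

    a, b = scheme.cross_pair
    da = tables.norm_array(a) - tables.means[a]
    db = tables.norm_array(b) - tables.means[b]
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    cross = np.abs(da[:, None] * db[None, :]) / denom
    return first + cross


def count_adjacent_pairs(sequence: str) -> PairCounts:
    """Directed counts of immediately adjacent residue pairs in ``sequence``."""
    if len(sequence) < 1:
        raise ValueError("sequence must have length >= 1")
    counts = np.zeros((N_RESIDUES, N_RESIDUES), dtype=np.int64)
    idx = np.fromiter((INDEX[c] for c in sequence), dtype=np.int64, count=len(sequence))
    if len(idx) >= 2:
        np.add.at(counts, (idx[:-1], idx[1:]), 1)
    return PairCounts(counts=counts)


def rho_from_counts(counts: PairCounts) -> RhoMatrix:
    """Existence indicator: rho[l, m] = 1 exactly when counts[l, m] > 0."""
    return RhoMatrix(rho=(counts.counts > 0).astype(np.int64))


def xy_sums(residue: str, counts: PairCounts, scheme: PairScheme, tables: PropertyTable) -> float:
    """Count-weighted neighbour sum {X + Y} for ``residue``.

    (1/38) * [ sum_{k != a} f(k->a) theta(k, a) + sum_{k != a} f(a->k) theta(a, k) ]

    with f taken from the adjacency counts; absent pairs contribute zero
    (the f_0 convention).  This single quantity weights every positional
    gap factor of the residue's feature component.
    """
    if residue not in INDEX:
        raise ValueError(f"unknown residue: {residue!r}")
    tmat = theta_matrix(scheme, tables)
    return float(xy_sums_all(counts, tmat)[INDEX[residue]])


def xy_sums_all(counts: PairCounts, tmat: np.ndarray) -> np.ndarray:
    """Vector of {X + Y} values for all 20 residues, given a precomputed theta matrix."""
    ft = counts.counts * tmat
    diag = np.diag(ft)
    incoming = ft.sum(axis=0) - diag  # sum over k != a of f(k->a) theta(k, a)
    outgoing = ft.sum(axis=1) - diag  # sum over k != a of f(a->k) theta(a, k)
    return (incoming + outgoing) / PAIR_CLASS_NORM
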