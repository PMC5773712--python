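"""The 220-element sequence encoder.

Each protein sequence S = x1 x2 ... xN is summarized by one feature
component Pi per residue type per property scheme, built from

* the occurrence count Lambda of the residue,
* a self-correlation term (Lambda - 1)! * theta(a, a), and
* positional gap factors -- the leading gap (p1 - 0), the internal gaps
  (p_{t+1} - p_t) between consecutive occurrences and the trailing gap
  (N - p_Lambda) -- each multiplied by the residue's count-weighted
  neighbour sum {X + Y} (see :mod:`sigpep.pairing`).

Boundary gaps are dropped when the first occurrence is at position 1 or
the last occurrence is terminal.  A residue that never occurs contributes
a zero component.

The full vector has 220 elements: for each of the three property schemes
(hydrophobicity, hydrophilicity, side-chain mass) the 20 components are
split into three additive sub-blocks -- core (count + self term +
internal-gap sum), leading-gap and trailing-gap -- giving 60 per property
(their sum recovers Pi exactly); the final 40 elements are the 20
length-normalized residue compositions and the 20 length-normalized mean
positions.

Sequences are truncated to their first 100 residues before encoding
(mirroring the curation rule), which bounds the factorial self-term;
factorials are evaluated in log space with a saturation cap of 1e300.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .pairing import SCHEMES, PairScheme, count_adjacent_pairs, theta_matrix, xy_sums_all
from .properties import ALPHABET, INDEX, N_RESIDUES, PROPERTY_NAMES, NON_STANDARD, PropertyTable

#: Total feature-vector length: 3 properties x 3 sub-blocks x 20 + 20 + 20.
N_FEATURES = 220

#: Truncation length applied before encoding (matches the curation rule).
DEFAULT_MAX_LEN = 100

#: Saturation bound for the factorial self-term (documented cap).
FACTORIAL_CAP = 1e300

_SUB_BLOCKS = ("core", "lead", "tail")


@dataclass(frozen=True)
class ProteinSequence:
    """A validated primary sequence over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = sorted({c for c in self.residues if c not in INDEX})
        if bad:
            kind = "non-standard" if set(bad) & NON_STANDARD else "invalid"
            raise ValueError(f"{self.id}: {kind} residues {bad}")

    @property
    def N(self) -> int:
        return len(self.residues)

    def truncated(self, max_len: int = DEFAULT_MAX_LEN) -> "ProteinSequence":
        if self.N <= max_len:
            return self
        return ProteinSequence(id=self.id, residues=self.residues[:max_len])


@dataclass(frozen=True)
class OccurrenceProfile:
    """Ascending 1-based positions of one residue type in a sequence."""

    residue: str
    positions: Tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class FeatureVector:
    """The 220-element encoding of one sequence."""

    id: str
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} elements")


def feature_names() -> List[str]:
    """Column names of the 220 features, in layout order."""
    names = []
    for scheme in SCHEMES:
        prop = PROPERTY_NAMES[scheme.scheme_id]
        for sub in _SUB_BLOCKS:
            names.extend(f"{prop}_{sub}_{res}" for res in ALPHABET)
    names.extend(f"composition_{res}" for res in ALPHABET)
    names.extend(f"position_{res}" for res in ALPHABET)
    return names


def occurrence_profile(seq: ProteinSequence, residue: str) -> OccurrenceProfile:
    """All and only the positions of ``residue``, 1-based, ascending."""
    if residue not in INDEX:
        raise ValueError(f"unknown residue: {residue!r}")
    positions = tuple(i + 1 for i, c in enumerate(seq.residues) if c == residue)
    return OccurrenceProfile(residue=residue, positions=positions)


def gap_terms(
    profile: OccurrenceProfile, N: int
) -> Optional[Tuple[Optional[float], Tuple[float, ...], Optional[float]]]:
    """Positional gap factors (leading, internal, trailing) for a profile.

    The leading gap p1 is retained only when the first occurrence is after
    position 1; the trailing gap N - p_Lambda only when the last occurrence
    is not terminal; dropped gaps are returned as None.  An empty profile
    returns None (the component is zero by convention).
    """
    if profile.count == 0:
        return None
    pos = profile.positions
    if pos[-1] > N:
        raise ValueError("profile positions exceed sequence length")
    leading = float(pos[0]) if pos[0] > 1 else None
    internal = tuple(float(pos[t + 1] - pos[t]) for t in range(len(pos) - 1))
    trailing = float(N - pos[-1]) if pos[-1] < N else None
    return leading, internal, trailing


def _factorial(n: int) -> float:
    """n! as a float, evaluated in log space, saturating at FACTORIAL_CAP."""
    if n < 0:
        raise ValueError("factorial of negative integer")
    log_f = math.lgamma(n + 1)
    if log_f > math.log(FACTORIAL_CAP):
        return FACTORIAL_CAP
    return math.exp(log_f)


def residue_component_parts(
    seq: ProteinSequence, residue: str, scheme: PairScheme, tables: PropertyTable
) -> Tuple[float, float, float]:
    """The three additive parts (core, leading, trailing) of Pi for one residue.

    core = Lambda + (Lambda-1)! * theta(a, a) + sum(internal gaps) * {X+Y};
    leading/trailing are the retained boundary gaps times {X+Y}.  Their sum
    is the full feature component Pi; all three are zero for an absent
    residue.
    """
    profile = occurrence_profile(seq, residue)
    gaps = gap_terms(profile, seq.N)
    if gaps is None:
        return 0.0, 0.0, 0.0
    leading, internal, trailing = gaps

    tmat = theta_matrix(scheme, tables)
    counts = count_adjacent_pairs(seq.residues)
    xy = float(xy_sums_all(counts, tmat)[INDEX[residue]])

    lam = profile.count
    core = lam + _factorial(lam - 1) * tmat[INDEX[residue], INDEX[residue]]
    core += sum(internal) * xy
    lead = leading * xy if leading is not None else 0.0
    tail = trailing * xy if trailing is not None else 0.0
    return core, lead, tail


def residue_component(
    seq: ProteinSequence, residue: str, scheme: PairScheme, tables: PropertyTable
) -> float:
    """The full feature component Pi for one residue under one scheme."""
    core, lead, tail = residue_component_parts(seq, residue, scheme, tables)
    return core + lead + tail


def encode(
    seq: ProteinSequence,
    tables: Optional[PropertyTable] = None,
    max_len: int = DEFAULT_MAX_LEN,
) -> FeatureVector:
    """Encode a sequence as its 220-element feature vector.

    Raises
    ------
    ValueError
        If the (truncated) sequence is shorter than 2 residues -- no
        adjacent pairs exist and the pair statistics are undefined.
    """
    if tables is None:
        tables = PropertyTable.load_default()
    seq = seq.truncated(max_len)
    N = seq.N
    if N < 2:
        raise ValueError(f"{seq.id}: need at least 2 residues to encode, got {N}")

    idx = np.fromiter((INDEX[c] for c in seq.residues), dtype=np.int64, count=N)
    counts = count_adjacent_pairs(seq.residues)

    # Per-residue positional summaries (1-based).
    lam = np.bincount(idx, minlength=N_RESIDUES).astype(float)
    first = np.full(N_RESIDUES, -1, dtype=np.int64)
    last = np.zeros(N_RESIDUES, dtype=np.int64)
    pos_sum = np.zeros(N_RESIDUES, dtype=float)
    for i in range(N - 1, -1, -1):
        first[idx[i]] = i + 1
    for i in range(N):
        last[idx[i]] = i + 1
        pos_sum[idx[i]] += i + 1
    present = lam > 0

    values = np.empty(N_FEATURES)
    offset = 0
    fact = np.array([_factorial(int(l) - 1) if l > 0 else 0.0 for l in lam])
    for scheme in SCHEMES:
        tmat = theta_matrix(scheme, tables)
        xy = xy_sums_all(counts, tmat)
        # Internal gaps telescope: sum of consecutive differences = last - first.
        internal_sum = np.where(present, (last - first).astype(float), 0.0)
        core = np.where(present, lam + fact * np.diag(tmat) + internal_sum * xy, 0.0)
        lead = np.where(present & (first > 1), first * xy, 0.0)
        tail = np.where(present & (last < N), (N - last) * xy, 0.0)
        values[offset : offset + 20] = core
        values[offset + 20 : offset + 40] = lead
        values[offset + 40 : offset + 60] = tail
        offset += 60

    values[offset : offset + 20] = lam / N
    offset += 20
    with np.errstate(invalid="ignore"):
        mean_pos = np.where(present, pos_sum / np.maximum(lam, 1.0), 0.0)
    values[offset : offset + 20] = mean_pos / N
    return FeatureVector(id=seq.id, values=values)


def encode_many(
    seqs,
    tables: Optional[PropertyTable] = None,
    max_len: int = DEFAULT_MAX_LEN,
) -> np.ndarray:
    """Encode a list of sequences into an (n, 220) feature matrix."""
    if tables is None:
        tables = PropertyTable.load_default()
    return np.vstack([encode(s, tables, max_len).values for s in seqs])
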