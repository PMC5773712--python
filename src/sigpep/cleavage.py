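"""Cleavage-site detection: log-odds weight matrix and the (-3, -1) rule.

Signal peptidase cleaves between the signal's -1 residue and the mature
protein's +1 residue.  Detection combines two ingredients:

* a position weight matrix Q(a, i) = ln(P(a, i) / <P(a)>) built from
  aligned training windows around known cleavage sites (P(a, i) is the
  positional count, <P(a)> the background abundance; an additive
  pseudocount keeps the logarithm finite), and
* hard residue-identity constraints at -1 and -3 with a proline exclusion
  in -3..+1 (the "(-3, -1) rule"), with separate eukaryotic and
  prokaryotic residue sets.

The scanner walks candidate sites (the signal may span 3-60 residues),
zeroes every position that fails the rule and scores the rest by summing
Q over the aligned window; the reported site is the spike -- the maximal
scoring compliant position, ties broken toward the N-terminus.

Positions are counted relative to the cleavage bond: "site" is the
1-based index of the +1 residue, so -1 is site-1 and -3 is site-3.

The eukaryotic -3 residue set is implemented as printed in the source
model (charged/polar residues), which differs from the classical
von Heijne small-residue rule; ``get_rules(..., classic_von_heijne=True)``
selects the classical sets instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .encoder import ProteinSequence
from .properties import ALPHABET, INDEX, N_RESIDUES

#: Signal peptides span 3-60 residues; candidate +1 sites are 4..61 at most.
MIN_SIGNAL_LEN = 3
MAX_SIGNAL_LEN = 60

#: Default aligned window relative to the cleavage bond (no position 0).
DEFAULT_POSITIONS = tuple(range(-13, 0)) + (1, 2)


@dataclass(frozen=True)
class RuleSet:
    """Residue-identity constraints around the cleavage bond."""

    organism: str
    allowed_minus1: frozenset
    allowed_minus3: frozenset
    forbidden_minus3: frozenset
    #: inclusive window (relative positions) in which proline is excluded.
    no_proline_window: Tuple[int, ...] = (-3, -2, -1, 1)
    #: soft preference (not enforced by rule_check): hydrophobic at -7/-8.
    hydrophobic_pref_positions: frozenset = frozenset()
    hydrophobic_pref_excluded: frozenset = frozenset()

    def __post_init__(self):
        if self.allowed_minus3 & self.forbidden_minus3:
            raise ValueError("allowed and forbidden -3 sets must be disjoint")


EUKARYOTE_RULES = RuleSet(
    organism="eukaryote",
    allowed_minus1=frozenset("ASGCT"),
    allowed_minus3=frozenset("DEKRNQ"),
    forbidden_minus3=frozenset("FHYW"),
)

PROKARYOTE_RULES = RuleSet(
    organism="prokaryote",
    allowed_minus1=frozenset("AGST"),
    allowed_minus3=frozenset("AGLSTV"),
    forbidden_minus3=frozenset(),
    hydrophobic_pref_positions=frozenset({-7, -8}),
    hydrophobic_pref_excluded=frozenset("VF"),
)

#: Classical small-residue alternative for eukaryotes (selectable by flag).
CLASSIC_VON_HEIJNE_RULES = RuleSet(
    organism="eukaryote",
    allowed_minus1=frozenset("AGSCT"),
    allowed_minus3=frozenset("AGSCTVLI"),
    forbidden_minus3=frozenset(),
)


def get_rules(organism: str, classic_von_heijne: bool = False) -> RuleSet:
    """Rule set for ``organism`` in {eukaryote, prokaryote}."""
    if organism == "eukaryote":
        return CLASSIC_VON_HEIJNE_RULES if classic_von_heijne else EUKARYOTE_RULES
    if organism == "prokaryote":
        return PROKARYOTE_RULES
    raise ValueError(f"unknown organism: {organism!r}")


@dataclass(frozen=True)
class CleavageModel:
    """Log-odds weight matrix over an aligned window around the cleavage bond."""

    Q: np.ndarray  # (20, len(positions))
    positions: Tuple[int, ...]
    pseudocount: float
    background: Dict[str, float]

    def __post_init__(self):
        if self.Q.shape != (N_RESIDUES, len(self.positions)):
            raise ValueError("Q shape must be (20, n_positions)")

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = "\t".join(f"{p:+d}" for p in self.positions)
            fh.write(f"# pseudocount={self.pseudocount}\n")
            fh.write("# background=" + ",".join(f"{r}:{self.background[r]:.6g}" for r in ALPHABET) + "\n")
            fh.write(f"residue\t{cols}\n")
            for i, res in enumerate(ALPHABET):
                row = "\t".join(f"{v:.10g}" for v in self.Q[i])
                fh.write(f"{res}\t{row}\n")

    @classmethod
    def load_tsv(cls, path) -> "CleavageModel":
        pseudocount = 0.0
        background = {}
        rows = {}
        positions = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# pseudocount="):
                    pseudocount = float(line.split("=", 1)[1])
                elif line.startswith("# background="):
                    for item in line.split("=", 1)[1].split(","):
                        res, val = item.split(":")
                        background[res] = float(val)
                elif line.startswith("residue\t"):
                    positions = tuple(int(p) for p in line.split("\t")[1:])
                elif line and not line.startswith("#"):
                    fields = line.split("\t")
                    rows[fields[0]] = [float(v) for v in fields[1:]]
        if positions is None:
            raise ValueError(f"malformed weight-matrix file: {path}")
        Q = np.array([rows[res] for res in ALPHABET])
        return cls(Q=Q, positions=positions, pseudocount=pseudocount, background=background)


def build_weight_matrix(
    aligned_windows: Sequence[str],
    background: Mapping[str, float],
    pseudocount: float = 1.0,
    positions: Tuple[int, ...] = DEFAULT_POSITIONS,
) -> CleavageModel:
    """Build Q from equal-length windows aligned on the cleavage bond.

    Q(a, i) = ln( (count(a, i) + pseudocount)
                  / (<P(a)> * (n_windows + 20 * pseudocount)) )

    With a zero pseudocount, zero counts produce -inf sentinels.  When the
    column frequencies equal the background exactly (pseudocount 0), Q is
    identically zero.
    """
    if not aligned_windows:
        raise ValueError("need at least one aligned window")
    width = len(aligned_windows[0])
    if any(len(w) != width for w in aligned_windows):
        raise ValueError("ragged aligned windows")
    if width != len(positions):
        raise ValueError(f"windows have width {width}, expected {len(positions)}")
    total_bg = sum(background[r] for r in ALPHABET)
    if any(background[r] <= 0 for r in ALPHABET) or not np.isclose(total_bg, 1.0):
        raise ValueError("background must be strictly positive and sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")

    counts = np.zeros((N_RESIDUES, width))
    for w in aligned_windows:
        for i, res in enumerate(w):
            counts[INDEX[res], i] += 1

    n = len(aligned_windows)
    bg = np.array([background[r] for r in ALPHABET])
    denom = bg[:, None] * (n + N_RESIDUES * pseudocount)
    numer = counts + pseudocount
    with np.errstate(divide="ignore"):
        Q = np.log(numer / denom)
    return CleavageModel(
        Q=Q, positions=tuple(positions), pseudocount=pseudocount,
        background={r: float(background[r]) for r in ALPHABET},
    )


def _candidate_range(N: int) -> range:
    return range(4, min(MAX_SIGNAL_LEN, N - 1) + 1)


def rule_check(seq: ProteinSequence, candidate_site: int, rules: RuleSet) -> bool:
    """True iff ``candidate_site`` satisfies the (-3, -1) constraints.

    The site is the 1-based index of the +1 residue; it must lie in
    [4, min(N-1, 60)] so that positions -3..+1 exist within the signal
    length bounds.
    """
    N = seq.N
    if candidate_site not in _candidate_range(N):
        raise ValueError(
            f"candidate site {candidate_site} outside [4, {min(MAX_SIGNAL_LEN, N - 1)}]"
        )
    s = seq.residues
    minus1 = s[candidate_site - 2]
    minus3 = s[candidate_site - 4]
    if minus1 not in rules.allowed_minus1:
        return False
    if minus3 not in rules.allowed_minus3 or minus3 in rules.forbidden_minus3:
        return False
    for rel in rules.no_proline_window:
        # rel < 0 -> signal side, rel >= 1 -> mature side (there is no position 0)
        idx = (candidate_site - 1) + (rel - 1 if rel > 0 else rel)
        if 0 <= idx < N and s[idx] == "P":
            return False
    return True


def window_score(seq: ProteinSequence, site: int, model: CleavageModel) -> float:
    """Sum of Q over the aligned window centered on the cleavage bond at ``site``.

    Window positions falling outside the sequence contribute nothing, so
    sites near the N-terminus are scored on their in-bounds positions.
    """
    s = seq.residues
    score = 0.0
    for col, rel in enumerate(model.positions):
        idx = (site - 1) + (rel - 1) if rel > 0 else (site - 1) + rel
        if 0 <= idx < seq.N:
            score += model.Q[INDEX[s[idx]], col]
    return score


def extract_window(seq: ProteinSequence, site: int, positions=DEFAULT_POSITIONS) -> Optional[str]:
    """The aligned window string at ``site``, or None if it runs out of bounds."""
    s = seq.residues
    chars = []
    for rel in positions:
        idx = (site - 1) + (rel - 1) if rel > 0 else (site - 1) + rel
        if not (0 <= idx < seq.N):
            return None
        chars.append(s[idx])
    return "".join(chars)


def scan_cleavage(
    seq: ProteinSequence, model: CleavageModel, rules: RuleSet
) -> Optional[Tuple[int, float]]:
    """Locate the cleavage site as the maximal-scoring rule-compliant position.

    Candidate +1 positions run over 4..min(60, N-1); positions failing the
    (-3, -1) rule are zeroed out of consideration.  Returns (site, score)
    for the spike, ties broken toward the most N-terminal site, or None
    when no candidate passes the rule.
    """
    if seq.N < 5:
        raise ValueError(f"{seq.id}: sequence too short to scan (N={seq.N})")
    best: Optional[Tuple[int, float]] = None
    for site in _candidate_range(seq.N):
        if not rule_check(seq, site, rules):
            continue
        score = window_score(seq, site, model)
        if best is None or score > best[1]:
            best = (site, score)
    return best


def windows_from_sites(
    seqs: Sequence[ProteinSequence],
    sites: Sequence[int],
    positions: Tuple[int, ...] = DEFAULT_POSITIONS,
) -> List[str]:
    """Extract full in-bounds training windows at known sites (others skipped)."""
    windows = []
    for seq, site in zip(seqs, sites):
        w = extract_window(seq, site, positions)
        if w is not None:
            windows.append(w)
    return windows


def residue_background(seqs: Sequence[ProteinSequence]) -> Dict[str, float]:
    """Observed residue frequencies over a set of sequences (for <P(a)>)."""
    counts = np.zeros(N_RESIDUES)
    for seq in seqs:
        for c in seq.residues:
            counts[INDEX[c]] += 1
    if counts.sum() == 0:
        raise ValueError("no residues")
    counts = np.maximum(counts, 1e-9)
    freqs = counts / counts.sum()
    return {res: float(freqs[i]) for i, res in enumerate(ALPHABET)}
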