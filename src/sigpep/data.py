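"""Sequence I/O, dataset curation and the synthetic-data generator.

Curation emulates the selection applied to a protein knowledgebase
export, supplied here as a documented TSV dialect with columns

    id  oc  location  signal_start  signal_end  keywords  sequence

(keywords semicolon-separated; signal_start/signal_end empty when no
signal-peptide feature is annotated).  Secretory records must carry a
signal annotation and none of the exclusion keywords ("potential",
"probable", "fragment", "by similarity"); their first 100 residues are
extracted.  Non-secretory records are nuclear or cytoplasmic for
eukaryotes and cytoplasmic for prokaryotes, and are not truncated.
Exact-duplicate sequences are removed in both roles.

The synthetic generator emulates the tripartite signal-peptide
architecture: a short basic n-region (1-5 residues, at least one K/R), a
central hydrophobic h-region (7-15 residues), and a polar c-region (3-7
residues) whose -3/-1 positions are drawn to satisfy the cleavage rule,
followed by a mature region of cytoplasmic-like composition.  Negatives
are plain cytoplasmic-like sequences with no planted signal.  Everything
is seeded and reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cleavage import get_rules, rule_check
from .encoder import ProteinSequence
from .properties import ALPHABET, INDEX, NON_STANDARD

logger = logging.getLogger("sigpep")

EXCLUSION_KEYWORDS = ("potential", "probable", "fragment", "by similarity")
TRUNCATION_LENGTH = 100

ANNOTATION_COLUMNS = ("id", "oc", "location", "signal_start", "signal_end", "keywords", "sequence")


# ---------------------------------------------------------------------------
# FASTA I/O

def _apply_residue_policy(seq_id: str, residues: str, policy: str, replacement: Optional[str]) -> str:
    if policy == "reject":
        return residues  # ProteinSequence validation raises on bad residues
    if policy == "replace":
        if replacement is None or replacement not in INDEX:
            raise ValueError("replace policy needs a canonical replacement residue")
        return "".join(replacement if c in NON_STANDARD else c for c in residues)
    raise ValueError(f"unknown residue policy: {policy!r}")


def read_fasta(path, policy: str = "reject", replacement: Optional[str] = None) -> List[ProteinSequence]:
    """Read protein sequences from FASTA.

    Duplicate ids are kept but suffixed (``_2``, ``_3``, ...) with a
    warning.  Non-standard residues (B, Z, X, U, O) raise per record under
    the default "reject" policy, or are mapped to ``replacement`` under
    "replace".
    """
    seen: Dict[str, int] = {}
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id = rec.id
        if rec_id in seen:
            seen[rec_id] += 1
            new_id = f"{rec_id}_{seen[rec_id]}"
            warnings.warn(f"duplicate FASTA id {rec_id!r}; renamed to {new_id!r}")
            rec_id = new_id
        else:
            seen[rec_id] = 1
        residues = _apply_residue_policy(rec_id, str(rec.seq).upper(), policy, replacement)
        out.append(ProteinSequence(id=rec_id, residues=residues))
    return out


def write_fasta(records: Sequence[ProteinSequence], path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    seq_records = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Curation

@dataclass(frozen=True)
class AnnotatedRecord:
    """One row of the annotation TSV."""

    id: str
    oc: str
    location: str
    signal_annotation: Optional[Tuple[int, int]]
    keywords: Tuple[str, ...]
    sequence: str

    def __post_init__(self):
        if self.signal_annotation is not None:
            start, end = self.signal_annotation
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(f"{self.id}: signal annotation outside sequence bounds")


def read_annotations(path) -> List[AnnotatedRecord]:
    """Parse the annotation TSV dialect (header required)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_COLUMNS:
            raise ValueError(f"annotation TSV must have columns {ANNOTATION_COLUMNS}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            rec_id, oc, location, start, end, keywords, sequence = fields
            signal = (int(start), int(end)) if start and end else None
            kw = tuple(k.strip() for k in keywords.split(";") if k.strip())
            records.append(
                AnnotatedRecord(rec_id, oc, location, signal, kw, sequence.upper())
            )
    return records


def _organism_matches(oc: str, organism: str) -> bool:
    oc_l = oc.lower()
    if organism == "eukaryote":
        return "eukary" in oc_l
    if organism == "gram_positive":
        return "gram-positive" in oc_l or "gram positive" in oc_l
    if organism == "gram_negative":
        return "gram-negative" in oc_l or "gram negative" in oc_l
    raise ValueError(f"unknown organism: {organism!r}")


def _has_exclusion_keyword(keywords: Sequence[str]) -> bool:
    joined = [k.lower() for k in keywords]
    return any(excl in k for k in joined for excl in EXCLUSION_KEYWORDS)


def curate(
    records: Sequence[AnnotatedRecord], role: str, organism: str = "eukaryote"
) -> List[ProteinSequence]:
    """Apply the selection filters and return curated sequences.

    role="secretory": keep records of the organism class with a
    signal-peptide annotation and no exclusion keyword, truncated to the
    first 100 residues.  role="non_secretory": keep records located in the
    nucleus or cytoplasm (cytoplasm only for prokaryotes), untruncated.
    Exact-duplicate sequences are dropped after filtering.
    """
    if role not in ("secretory", "non_secretory"):
        raise ValueError(f"role must be secretory or non_secretory, got {role!r}")
    kept = []
    n_in = len(records)
    for rec in records:
        if not _organism_matches(rec.oc, organism):
            continue
        if _has_exclusion_keyword(rec.keywords):
            continue
        if role == "secretory":
            if rec.signal_annotation is None:
                continue
            residues = rec.sequence[:TRUNCATION_LENGTH]
        else:
            loc = rec.location.lower()
            if organism == "eukaryote":
                if not ("nucleus" in loc or "cytoplasm" in loc):
                    continue
            else:
                if "cytoplasm" not in loc:
                    continue
            residues = rec.sequence
        kept.append(ProteinSequence(id=rec.id, residues=residues))

    seen = set()
    unique = []
    for seq in kept:
        if seq.residues in seen:
            continue
        seen.add(seq.residues)
        unique.append(seq)
    logger.info(
        "curate(role=%s, organism=%s): %d records in, %d after filters, %d unique",
        role, organism, n_in, len(kept), len(unique),
    )
    return unique


# ---------------------------------------------------------------------------
# Synthetic generator

#: Cytoplasmic-like residue composition (typical globular-protein frequencies).
CYTOPLASMIC_COMPOSITION: Dict[str, float] = {
    "A": 0.080, "R": 0.055, "N": 0.040, "D": 0.055, "C": 0.015,
    "Q": 0.040, "E": 0.070, "G": 0.070, "H": 0.025, "I": 0.060,
    "K": 0.060, "L": 0.090, "M": 0.025, "F": 0.040, "P": 0.045,
    "S": 0.065, "T": 0.055, "W": 0.010, "V": 0.070, "Y": 0.030,
}

#: Hydrophobic pool for the h-region, leucine-rich as in real signals.
H_REGION_POOL = {
    "L": 0.35, "A": 0.20, "V": 0.14, "I": 0.10, "F": 0.09,
    "M": 0.05, "W": 0.03, "C": 0.04,
}

#: Basic/neutral pool for the n-region.
N_REGION_POOL = {
    "M": 0.25, "K": 0.20, "R": 0.20, "A": 0.10, "S": 0.10,
    "T": 0.05, "N": 0.05, "Q": 0.05,
}

#: Polar, proline-free pool for c-region filler positions.
C_REGION_POOL = {
    "A": 0.20, "S": 0.18, "G": 0.14, "T": 0.12, "N": 0.10,
    "Q": 0.10, "H": 0.06, "V": 0.10,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generated datasets."""

    n_region_len: Tuple[int, int] = (1, 5)
    h_region_len: Tuple[int, int] = (7, 15)
    c_region_len: Tuple[int, int] = (3, 7)
    mature_len: Tuple[int, int] = (30, 80)
    negative_len: Tuple[int, int] = (50, 150)
    organism: str = "eukaryote"
    seed: int = 0
    n_pos: int = 200
    n_neg: int = 200

    def __post_init__(self):
        for name in ("n_region_len", "h_region_len", "c_region_len", "mature_len", "negative_len"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.c_region_len[0] < 3:
            raise ValueError("c-region must be at least 3 residues to host -3..-1")
        total_min = self.n_region_len[0] + self.h_region_len[0] + self.c_region_len[0]
        total_max = self.n_region_len[1] + self.h_region_len[1] + self.c_region_len[1]
        if not (3 <= total_min and total_max <= 60):
            raise ValueError("total signal length must stay within 3-60 residues")
        if self.mature_len[0] < 2:
            raise ValueError("mature region must be at least 2 residues")


def _draw(rng: np.random.Generator, pool: Dict[str, float], k: int) -> List[str]:
    residues = list(pool)
    probs = np.array([pool[r] for r in residues])
    probs = probs / probs.sum()
    return list(rng.choice(residues, size=k, p=probs))


def generate_synthetic(
    spec: SyntheticSpec,
) -> Tuple[List[ProteinSequence], List[int], List[ProteinSequence]]:
    """Generate (positives, planted_sites, negatives) under ``spec``.

    Each positive is n-region + h-region + c-region + mature region; the
    planted cleavage site (1-based index of the first mature residue) is
    recorded and rule-compliant by construction.  Negatives are drawn from
    a cytoplasmic-like composition with no planted signal.
    """
    rng = np.random.default_rng(spec.seed)
    rules = get_rules("eukaryote" if spec.organism == "eukaryote" else "prokaryote")

    positives: List[ProteinSequence] = []
    sites: List[int] = []
    for i in range(spec.n_pos):
        n_len = int(rng.integers(spec.n_region_len[0], spec.n_region_len[1] + 1))
        h_len = int(rng.integers(spec.h_region_len[0], spec.h_region_len[1] + 1))
        c_len = int(rng.integers(spec.c_region_len[0], spec.c_region_len[1] + 1))
        m_len = int(rng.integers(spec.mature_len[0], spec.mature_len[1] + 1))

        n_region = _draw(rng, N_REGION_POOL, n_len)
        if not set(n_region) & {"K", "R"}:
            n_region[int(rng.integers(n_len))] = str(rng.choice(["K", "R"]))
        h_region = _draw(rng, H_REGION_POOL, h_len)
        c_region = _draw(rng, C_REGION_POOL, c_len)
        minus3_pool = sorted(rules.allowed_minus3 - rules.forbidden_minus3)
        c_region[-3] = str(rng.choice(minus3_pool))
        c_region[-1] = str(rng.choice(sorted(rules.allowed_minus1)))

        mature = _draw(rng, CYTOPLASMIC_COMPOSITION, m_len)
        while mature[0] == "P":  # proline exclusion extends to +1
            mature[0] = _draw(rng, CYTOPLASMIC_COMPOSITION, 1)[0]

        residues = "".join(n_region + h_region + c_region + mature)
        site = n_len + h_len + c_len + 1
        seq = ProteinSequence(id=f"pos_{i:04d}", residues=residues)
        if not rule_check(seq, site, rules):  # pragma: no cover - by construction
            raise RuntimeError("generated positive violates the cleavage rule")
        positives.append(seq)
        sites.append(site)

    negatives = []
    for i in range(spec.n_neg):
        length = int(rng.integers(spec.negative_len[0], spec.negative_len[1] + 1))
        residues = "".join(_draw(rng, CYTOPLASMIC_COMPOSITION, length))
        negatives.append(ProteinSequence(id=f"neg_{i:04d}", residues=residues))
    return positives, sites, negatives


def write_sites_tsv(positives: Sequence[ProteinSequence], sites: Sequence[int], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsite\n")
        for seq, site in zip(positives, sites):
            fh.write(f"{seq.id}\t{site}\n")


def read_sites_tsv(path) -> Dict[str, int]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                rec_id, site = line.rstrip("\n").split("\t")
                out[rec_id] = int(site)
    return out
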