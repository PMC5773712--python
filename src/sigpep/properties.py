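"""Residue alphabet and normalized physicochemical property scales.

The encoder works on three per-residue attributes -- hydrophobicity
(Tanford), hydrophilicity (Hopp-Woods) and side-chain mass -- each
standardized by an affine map onto the symmetric interval [-R, R]:

    d*(a) = [2R / (d_max - d_min)] * (d(a) - d_max) + R

so the most extreme residues sit exactly at +R and -R.  R defaults to 1,
which keeps pair-function magnitudes comparable across the three scales;
it is exposed as a parameter because the normalization is parametric in it.

Raw scale values are shipped as a plain-text TSV bundled with the package
(``data/property_scales.tsv``) so every downstream feature value is
reproducible against a versioned table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping

import numpy as np

#: The 20 canonical residues, one-letter codes, alphabetical order.
ALPHABET: tuple = tuple("ACDEFGHIKLMNPQRSTVWY")

#: residue -> ordinal 1..20 (alphabetical ordinal used throughout).
ORDINAL: Dict[str, int] = {res: i + 1 for i, res in enumerate(ALPHABET)}

#: residue -> 0-based array index.
INDEX: Dict[str, int] = {res: i for i, res in enumerate(ALPHABET)}

N_RESIDUES = 20

# Property identifiers (order fixed: it defines the feature-vector layout).
HYDROPHOBICITY = 1
HYDROPHILICITY = 2
SIDE_CHAIN_MASS = 3
PROPERTY_IDS = (HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS)
PROPERTY_NAMES = {
    HYDROPHOBICITY: "hydrophobicity",
    HYDROPHILICITY: "hydrophilicity",
    SIDE_CHAIN_MASS: "side_chain_mass",
}

#: Residues outside the canonical alphabet (ambiguity/rare codes).
NON_STANDARD = frozenset("BZXUO")


class DegenerateScaleError(ValueError):
    """Raised when a raw property scale has max == min (cannot be normalized)."""


def normalize_property(raw_values: Mapping[str, float], R: float = 1.0) -> Dict[str, float]:
    """Affinely map a raw 20-residue scale onto [-R, R].

    The residue with the maximal raw value maps to exactly +R, the minimal
    one to exactly -R; the map is order preserving.

    Parameters
    ----------
    raw_values
        Mapping residue -> raw scale value; must cover all 20 residues.
    R
        Positive half-width of the target range.

    Raises
    ------
    ValueError
        If a residue is missing or R <= 0.
    DegenerateScaleError
        If all raw values are equal.
    """
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    missing = [res for res in ALPHABET if res not in raw_values]
    if missing:
        raise ValueError(f"raw scale missing residues: {missing}")
    vals = {res: float(raw_values[res]) for res in ALPHABET}
    d_max = max(vals.values())
    d_min = min(vals.values())
    if d_max == d_min:
        raise DegenerateScaleError("degenerate scale: max == min")
    scale = 2.0 * R / (d_max - d_min)
    return {res: scale * (v - d_max) + R for res, v in vals.items()}


def property_mean(normalized: Mapping[str, float]) -> float:
    """Arithmetic mean of a normalized scale over the 20 residues."""
    missing = [res for res in ALPHABET if res not in normalized]
    if missing:
        raise ValueError(f"normalized scale missing residues: {missing}")
    return sum(float(normalized[res]) for res in ALPHABET) / N_RESIDUES


@dataclass(frozen=True)
class PropertyTable:
    """Raw and normalized values for the three physicochemical attributes.

    Attributes
    ----------
    raw
        property id -> {residue -> raw value}.
    normalized
        property id -> {residue -> value in [-R, R]}.
    means
        property id -> mean of the normalized values over the 20 residues.
    R
        Standardization half-width.
    """

    raw: Dict[int, Dict[str, float]]
    normalized: Dict[int, Dict[str, float]]
    means: Dict[int, float]
    R: float
    _arrays: Dict[int, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_raw(cls, raw: Mapping[int, Mapping[str, float]], R: float = 1.0) -> "PropertyTable":
        normalized = {s: normalize_property(raw[s], R) for s in PROPERTY_IDS}
        means = {s: property_mean(normalized[s]) for s in PROPERTY_IDS}
        table = cls(
            raw={s: dict(raw[s]) for s in PROPERTY_IDS},
            normalized=normalized,
            means=means,
            R=R,
        )
        for s in PROPERTY_IDS:
            table._arrays[s] = np.array([normalized[s][res] for res in ALPHABET])
        return table

    @classmethod
    def load_default(cls, R: float = 1.0) -> "PropertyTable":
        """Load the bundled Tanford / Hopp-Woods / side-chain-mass tables."""
        text = (resources.files("sigpep") / "data" / "property_scales.tsv").read_text()
        raw: Dict[int, Dict[str, float]] = {s: {} for s in PROPERTY_IDS}
        header = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            res = fields[0]
            raw[HYDROPHOBICITY][res] = float(fields[1])
            raw[HYDROPHILICITY][res] = float(fields[2])
            raw[SIDE_CHAIN_MASS][res] = float(fields[3])
        return cls.from_raw(raw, R)

    def norm_array(self, s: int) -> np.ndarray:
        """Normalized values of property ``s`` as a length-20 array in alphabet order."""
        return self._arrays[s]
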