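"""Monoisotopic mass arithmetic, glycan composition algebra, and the N-sequon rule.

Everything downstream (mass-gap candidate generation, fragment prediction,
modification bookkeeping) is built on the small amount of chemistry in this
module: an atomic monoisotopic-mass table, elemental compositions, amino-acid
residue masses, the four monosaccharide residues that make up an N-glycan
composition (Hex, HexNAc, Fuc, NeuAc), and the NxS/T sequon test.

Masses follow the Unimod atomic-mass convention so that the standard
modification constants used in iTRAQ glycoproteomics reproduce exactly at
their conventional printed precision:

* carbamidomethyl (C)      +57.021464 Da
* oxidation (M)            +15.9949 Da
* iTRAQ 4-plex label       +144.102063 Da
* deamidation (N/Q)        +0.984016 Da  (the PNGase-F scar marking a glycosite)
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MONOISOTOPIC",
    "PROTON_MASS",
    "NEUTRON_MASS",
    "WATER_MASS",
    "ElementalComposition",
    "GlycanComposition",
    "GlycositePeptide",
    "GLYCAN_TYPES",
    "monoisotopic_mass",
    "glycan_residue_mass",
    "classify_glycan",
    "has_nglyco_motif",
    "motif_rate",
    "peptide_backbone_mass",
    "AA_RESIDUE_MASS",
    "CARBAMIDOMETHYL",
    "OXIDATION",
    "ITRAQ4PLEX",
    "DEAMIDATION_MASS",
    "MONOSACCHARIDES",
]

# Monoisotopic atomic masses (Unimod convention; Da). Heavy isotopes are
# written with the nucleon number prefixed, e.g. "13C".
MONOISOTOPIC: dict[str, float] = {
    "H": 1.007825035,
    "C": 12.0,
    "13C": 13.00335483,
    "N": 14.003074,
    "15N": 15.00010897,
    "O": 15.99491463,
    "18O": 17.9991603,
    "S": 31.9720707,
    "P": 30.973762,
}

PROTON_MASS = 1.00727646688
NEUTRON_MASS = 1.00866491588

_FORMULA_TOKEN = re.compile(r"(\d*)([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """A multiset of atoms, e.g. ``C2H3NO`` for the carbamidomethyl group.

    Counts must be non-negative; mass differences (such as deamidation,
    +O −N −H) are expressed as the difference of two compositions rather
    than as negative counts.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = {e: int(c) for e, c in self.element_counts.items() if c}
        for element, count in counts.items():
            if count < 0:
                raise ValueError(f"negative count for element {element!r}")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse ``"C2H3NO"`` or space-separated ``"H12 C4 13C3 N 15N O"``.

        An isotope is written with its nucleon number before the symbol.
        """
        counts: Counter[str] = Counter()
        for token in formula.split():
            pos = 0
            while pos < len(token):
                m = _FORMULA_TOKEN.match(token, pos)
                if m is None or m.group(2) not in _BARE_SYMBOLS:
                    raise ValueError(f"cannot parse formula {formula!r} at {token[pos:]!r}")
                isotope, symbol, count = m.groups()
                key = f"{isotope}{symbol}" if isotope else symbol
                if key not in MONOISOTOPIC:
                    raise ValueError(f"unknown element symbol {key!r}")
                counts[key] += int(count) if count else 1
                pos = m.end()
        return cls(dict(counts))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = Counter(self.element_counts)
        counts.update(other.element_counts)
        return ElementalComposition(dict(counts))

    def __bool__(self) -> bool:
        return bool(self.element_counts)


_BARE_SYMBOLS = {k.lstrip("0123456789") for k in MONOISOTOPIC}


def monoisotopic_mass(comp: ElementalComposition | Mapping[str, int]) -> float:
    """Exact sum of count x atomic monoisotopic mass, in Da.

    Additive by construction: ``mass(a + b) == mass(a) + mass(b)`` up to
    float rounding. Unknown element symbols raise ``ValueError`` naming
    the symbol.
    """
    counts = comp.element_counts if isinstance(comp, ElementalComposition) else comp
    total = 0.0
    for element, count in counts.items():
        try:
            total += count * MONOISOTOPIC[element]
        except KeyError:
            raise ValueError(f"unknown element symbol {element!r}") from None
    return total


# ---------------------------------------------------------------------------
# Standard modification deltas (Da), derived from elemental compositions.

CARBAMIDOMETHYL = ElementalComposition.from_formula("C2H3NO").mass
OXIDATION = ElementalComposition.from_formula("O").mass
ITRAQ4PLEX = ElementalComposition.from_formula("H12 C4 13C3 N 15N O").mass
#: Deamidation of Asn/Gln: +O, -N, -H — the scar PNGase F leaves at a glycosite.
DEAMIDATION_MASS = (
    ElementalComposition.from_formula("O").mass
    - ElementalComposition.from_formula("NH").mass
)

WATER_MASS = ElementalComposition.from_formula("H2O").mass

# Amino-acid residue (dehydrated) elemental compositions, 20 standard letters.
_AA_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}
AA_RESIDUE_MASS: dict[str, float] = {
    aa: ElementalComposition.from_formula(f).mass for aa, f in _AA_FORMULAS.items()
}


# ---------------------------------------------------------------------------
# Glycan compositions

#: Monosaccharide residue (dehydrated) masses, Da.
MONOSACCHARIDES: dict[str, float] = {
    "hex": ElementalComposition.from_formula("C6H10O5").mass,
    "hexnac": ElementalComposition.from_formula("C8H13NO5").mass,
    "fuc": ElementalComposition.from_formula("C6H10O4").mass,
    "neuac": ElementalComposition.from_formula("C11H17NO8").mass,
}

GLYCAN_TYPES = (
    "high_mannose",
    "fucosylated_only",
    "sialylated_only",
    "fuco_sialylated",
    "other_complex_hybrid",
)


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """An N-glycan as monosaccharide counts (no topology): Hex / HexNAc / Fuc / NeuAc."""

    hex: int = 0
    hexnac: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hex", "hexnac", "fuc", "neuac"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} count")

    @property
    def residue_mass(self) -> float:
        return glycan_residue_mass(self)

    @property
    def n_residues(self) -> int:
        return self.hex + self.hexnac + self.fuc + self.neuac

    @property
    def glycan_type(self) -> str:
        return classify_glycan(self)

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.hex, self.hexnac, self.fuc, self.neuac)

    def __str__(self) -> str:  # e.g. "H5N4F1S2"
        return f"H{self.hex}N{self.hexnac}F{self.fuc}S{self.neuac}"


def glycan_residue_mass(g: GlycanComposition) -> float:
    """Added (dehydrated) mass of the glycan on a peptide, in Da."""
    return (
        g.hex * MONOSACCHARIDES["hex"]
        + g.hexnac * MONOSACCHARIDES["hexnac"]
        + g.fuc * MONOSACCHARIDES["fuc"]
        + g.neuac * MONOSACCHARIDES["neuac"]
    )


def classify_glycan(g: GlycanComposition) -> str:
    """Assign one of the five composition-level glycan-type labels.

    The partition is total: high-mannose glycans are the classic
    Man5–Man9 series (HexNAc2, 5–9 Hex, nothing else); any fucose without
    sialic acid is "fucosylated_only"; sialic acid without fucose is
    "sialylated_only"; both together are "fuco_sialylated"; everything
    else is a generic complex/hybrid composition.
    """
    if g.hexnac == 2 and 5 <= g.hex <= 9 and g.fuc == 0 and g.neuac == 0:
        return "high_mannose"
    if g.fuc >= 1 and g.neuac >= 1:
        return "fuco_sialylated"
    if g.fuc >= 1:
        return "fucosylated_only"
    if g.neuac >= 1:
        return "sialylated_only"
    return "other_complex_hybrid"


# ---------------------------------------------------------------------------
# Peptides and the N-glycosylation sequon

_STANDARD_AA = set(_AA_FORMULAS)


@dataclass(frozen=True)
class GlycositePeptide:
    """A glycosite-containing peptide backbone.

    ``glycosite_index`` is the 0-based position of the modified Asn (which
    may be recorded as Asp after deamidation bookkeeping in SPEG data).
    """

    sequence: str
    glycosite_index: int
    protein_id: str = ""
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _STANDARD_AA
        if bad:
            raise ValueError(f"non-standard residues in {self.sequence!r}: {sorted(bad)}")
        if not 0 <= self.glycosite_index < len(self.sequence):
            raise ValueError(
                f"glycosite index {self.glycosite_index} out of bounds for "
                f"{self.sequence!r}"
            )
        if self.sequence[self.glycosite_index] not in ("N", "D"):
            raise ValueError(
                f"residue at glycosite {self.glycosite_index} of {self.sequence!r} "
                "is neither N nor D"
            )

    @property
    def backbone_mass(self) -> float:
        """Neutral peptide mass with the standard fixed modifications applied."""
        return peptide_backbone_mass(self.sequence)

    def has_motif(self) -> bool:
        return has_nglyco_motif(self.sequence, self.glycosite_index)


def peptide_backbone_mass(
    sequence: str,
    *,
    itraq_nterm: bool = True,
    itraq_lys: bool = True,
    carbamidomethyl_cys: bool = True,
    oxidation_met: bool = True,
) -> float:
    """Neutral monoisotopic peptide mass with the study's fixed modifications.

    Defaults mirror an iTRAQ 4-plex experiment: label on the N-terminus and
    every Lys, carbamidomethyl on every Cys, and Met carried as the oxidized
    form. Deamidation is NOT applied here; for intact glycopeptides the
    glycan occupies the Asn, and for SPEG data the deamidation delta is
    added explicitly by the caller.
    """
    try:
        mass = sum(AA_RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in {sequence!r}") from None
    if itraq_nterm:
        mass += ITRAQ4PLEX
    if itraq_lys:
        mass += ITRAQ4PLEX * sequence.count("K")
    if carbamidomethyl_cys:
        mass += CARBAMIDOMETHYL * sequence.count("C")
    if oxidation_met:
        mass += OXIDATION * sequence.count("M")
    return mass


def has_nglyco_motif(sequence: str, site: int) -> bool:
    """True iff ``site`` sits in an NxS/T sequon (x any residue except Pro).

    ``site`` must index an N (or the D left by deamidation) within the
    sequence; the sequon requires two following residues on the same peptide.
    """
    if not 0 <= site < len(sequence):
        raise ValueError(f"site {site} out of bounds for sequence of length {len(sequence)}")
    if sequence[site] not in ("N", "D"):
        return False
    if site + 2 >= len(sequence):
        return False
    return sequence[site + 1] != "P" and sequence[site + 2] in ("S", "T")


def motif_rate(peptides: Sequence[tuple[str, int]] | Iterable[tuple[str, int]]) -> float:
    """Percentage of (sequence, site) pairs carrying the NxS/T sequon, to one decimal."""
    peptides = list(peptides)
    if not peptides:
        raise ValueError("motif_rate requires a non-empty peptide list")
    n_pass = sum(has_nglyco_motif(seq, site) for seq, site in peptides)
    return round(100.0 * n_pass / len(peptides), 1)
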