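"""Elemental compositions, masses and negative-mode ESI charge ladders.

Masses follow the neutral free-acid convention: every sulfo group is
counted as -SO3H and every carboxyl as -COOH.  This is the convention
under which the calculated mass of the library's reference hexasaccharide
(1900.6 Da average) matches the deconvoluted ESI-MS value.  Chains are
condensation products: the composition of an n-mer is the sum of the free
monosaccharide formulas minus (n-1) waters; an aglycone is condensed onto
the reducing end with the loss of one further water.

Average atomic weights are the IUPAC 2013 conventional values; the
monoisotopic scale uses the principal-isotope masses.  Sulfated
oligosaccharides are S-rich, so the monoisotopic mass of a library
compound sits ~1-2 Da below the average mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .glycans import Aglycone, NSub, Oligosaccharide, Ring

# IUPAC 2013 conventional atomic weights, 5 decimals.
AVERAGE_WEIGHTS = {
    "C": 12.011, "H": 1.008, "N": 14.007,
    "O": 15.999, "S": 32.06, "F": 18.99840,
}
# Principal-isotope (monoisotopic) masses.
MONOISOTOPIC_MASSES = {
    "C": 12.0, "H": 1.00783, "N": 14.00307,
    "O": 15.99491, "S": 31.97207, "F": 18.99840,
}
# Hydrogen atomic mass used for [M - zH]^z- ladders.
M_H = 1.00794


@dataclass(frozen=True)
class ElementalComposition:
    """Integer element counts (F covers the transient GlcNTFA residue)."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    f: int = 0

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s, self.f + other.f)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(
            self.c - other.c, self.h - other.h, self.n - other.n,
            self.o - other.o, self.s - other.s, self.f - other.f)
        if min(out.c, out.h, out.n, out.o, out.s, out.f) < 0:
            raise ValueError("negative element count")
        return out

    def as_dict(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n,
                "O": self.o, "S": self.s, "F": self.f}

    @property
    def formula(self) -> str:
        """Hill-order formula string, e.g. ``C18H24N4O8``."""
        parts = []
        for el in ("C", "H", "F", "N", "O", "S"):
            cnt = self.as_dict()[el]
            if cnt:
                parts.append(el + (str(cnt) if cnt != 1 else ""))
        return "".join(parts)

    def mass(self, weights: dict[str, float]) -> float:
        return sum(weights[el] * cnt for el, cnt in self.as_dict().items())


WATER = ElementalComposition(h=2, o=1)
SULFO = ElementalComposition(s=1, o=3)  # -SO3 increment (as free acid -SO3H)

# Free (underivatised) monosaccharides.
_URONIC_FREE = ElementalComposition(c=6, h=10, o=7)        # C6H10O7
_GLCN_FREE = ElementalComposition(c=6, h=13, n=1, o=5)     # C6H13NO5, free amine
_ACETYL = ElementalComposition(c=2, h=2, o=1)              # NH2 -> NHAc
# N-trifluoroacetylation replaces one amine H with COCF3: +C2, -H, +O, +F3.
_TFA_ADD = ElementalComposition(c=2, o=1, f=3)
_ONE_H = ElementalComposition(h=1)

# Aglycones as free phenols; condensation removes one water.
_AGLYCONE_FREE = {
    Aglycone.PNA_N3: ElementalComposition(c=12, h=16, n=4, o=2),  # C12H16N4O2
    Aglycone.PNP: ElementalComposition(c=6, h=5, n=1, o=3),       # C6H5NO3
    Aglycone.FREE: None,
}


def residue_composition(residue) -> ElementalComposition:
    """Composition of the free monosaccharide (before condensation)."""
    if residue.is_uronic:
        comp = _URONIC_FREE
    else:
        comp = _GLCN_FREE
        if residue.n_sub is NSub.ACETYL:
            comp = comp + _ACETYL
        elif residue.n_sub is NSub.SULFO:
            comp = comp + SULFO
        elif residue.n_sub is NSub.TFA:
            comp = comp + _TFA_ADD - _ONE_H
    for _ in residue.o_sulfo:
        comp = comp + SULFO
    return comp


def elemental_composition(oligo: Oligosaccharide) -> ElementalComposition:
    """Free-acid composition of the chain plus aglycone."""
    comp = ElementalComposition()
    for r in oligo:
        comp = comp + residue_composition(r)
    for _ in range(len(oligo) - 1):
        comp = comp - WATER
    agl = _AGLYCONE_FREE[oligo.aglycone]
    if agl is not None:
        comp = comp + agl - WATER
    return comp


@dataclass(frozen=True)
class MassResult:
    average_mass: float
    monoisotopic_mass: float
    composition: ElementalComposition


def mass_result(oligo: Oligosaccharide) -> MassResult:
    """Average and monoisotopic mass from one elemental composition."""
    comp = elemental_composition(oligo)
    return MassResult(
        average_mass=comp.mass(AVERAGE_WEIGHTS),
        monoisotopic_mass=comp.mass(MONOISOTOPIC_MASSES),
        composition=comp,
    )


def average_mass(oligo: Oligosaccharide) -> float:
    return mass_result(oligo).average_mass


def monoisotopic_mass(oligo: Oligosaccharide) -> float:
    return mass_result(oligo).monoisotopic_mass


def esi_ladder(mass: float, charges) -> list[tuple[int, float]]:
    """Negative-mode [M - zH]^z- ladder, sorted by charge.

    m/z = (M - z * m_H) / z for each requested z; m/z strictly decreases
    with z, which is how multiply charged envelopes are read off a
    deconvoluted spectrum.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    zs = sorted(set(int(z) for z in charges))
    if not zs:
        raise ValueError("at least one charge state required")
    if zs[0] < 1:
        raise ValueError("charge states must be positive integers")
    return [(z, (mass - z * M_H) / z) for z in zs]
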