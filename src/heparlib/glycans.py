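"""Sequence model for heparan sulfate (HS) and heparin oligosaccharides.

HS/heparin chains are linear (1->4)-linked polymers of alternating uronic
acid residues -- beta-D-glucuronic acid (GlcA) or its C5 epimer
alpha-L-iduronic acid (IdoA) -- and alpha-D-glucosamine (GlcN) residues.
Glucosamine nitrogens carry an acetyl, sulfo, trifluoroacetyl (a transient
protecting group used during chemoenzymatic synthesis) or free-amine state;
O-sulfo groups sit at position 2 of uronic acids and positions 3 and 6 of
glucosamines.  Sequences are written and stored from the non-reducing end
(where enzymatic elongation occurs) to the reducing end, which may carry a
UV-detectable aglycone tag.  Residues are labelled A, B, C, ... from the
non-reducing end, matching the convention used for NMR assignment.

The text grammar joins residue tokens with ``(1-4)`` (``(1->4)`` and the
typographic arrow are accepted on input) and appends ``-pNA-N3`` or
``-pNP`` for the aglycone, e.g.::

    GlcNS6S(1-4)GlcA(1-4)GlcNS3S6S(1-4)IdoA2S(1-4)GlcNS6S(1-4)GlcA-pNA-N3
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass


class GlycanError(ValueError):
    """Base class for sequence-model errors."""


class GrammarError(GlycanError):
    """The sequence text does not conform to the grammar."""


class ValidationError(GlycanError):
    """A structurally invalid residue or chain."""


class Ring(enum.Enum):
    """Monosaccharide ring type."""

    GLUCO_URONIC = "GlcA"
    IDO_URONIC = "IdoA"
    GLUCOSAMINE = "GlcN"

    @property
    def is_uronic(self) -> bool:
        return self is not Ring.GLUCOSAMINE


class NSub(enum.Enum):
    """Nitrogen substituent of a glucosamine (uronic acids use NONE)."""

    NONE = "none"
    ACETYL = "Ac"
    SULFO = "S"
    TFA = "TFA"
    FREE_AMINE = ""


class Aglycone(enum.Enum):
    """Reducing-end tag.

    PNA_N3 is N-(6-azidohexanamidyl) p-aminophenyl, the UV-detectable,
    azide-bearing tag carried by every library compound; PNP is the
    p-nitrophenyl tag used in earlier chemoenzymatic work.
    """

    PNA_N3 = "pNA-N3"
    PNP = "pNP"
    FREE = ""


_URONIC_RE = re.compile(r"^(GlcA|IdoA)(2S)?$")
_AMINE_RE = re.compile(r"^GlcN(TFA|Ac|S)?(3S)?(6S)?$")


@dataclass(frozen=True)
class Residue:
    """One monosaccharide residue.

    ``o_sulfo`` holds the O-sulfated ring positions ({2} for uronic acids,
    subsets of {3, 6} for glucosamines).  The anomeric configuration is
    derived from the ring type: GlcA-type residues are beta-linked, IdoA-
    and GlcN-type residues alpha-linked.
    """

    ring: Ring
    n_sub: NSub = NSub.NONE
    o_sulfo: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "o_sulfo", frozenset(self.o_sulfo))
        if self.ring.is_uronic:
            if self.n_sub is not NSub.NONE:
                raise ValidationError(
                    f"uronic residue cannot carry N-substituent {self.n_sub}")
            if not self.o_sulfo <= {2}:
                raise ValidationError(
                    f"illegal O-sulfo positions {sorted(self.o_sulfo)} for a "
                    "uronic residue (only 2-O allowed)")
        else:
            if self.n_sub is NSub.NONE:
                raise ValidationError(
                    "glucosamine requires an N-state (Ac, S, TFA or free amine)")
            if not self.o_sulfo <= {3, 6}:
                raise ValidationError(
                    f"illegal O-sulfo positions {sorted(self.o_sulfo)} for a "
                    "glucosamine residue (only 3-O/6-O allowed)")
            if 3 in self.o_sulfo and self.n_sub is not NSub.SULFO:
                raise ValidationError(
                    "a 3-O-sulfo glucosamine must be N-sulfated")

    @property
    def anomeric_config(self) -> str:
        """'beta' for gluco-uronic residues, 'alpha' otherwise."""
        return "beta" if self.ring is Ring.GLUCO_URONIC else "alpha"

    @property
    def is_uronic(self) -> bool:
        return self.ring.is_uronic

    @property
    def n_sulfo(self) -> bool:
        return self.n_sub is NSub.SULFO

    @property
    def sulfo_count(self) -> int:
        """Total sulfo groups on this residue (N- plus O-)."""
        return len(self.o_sulfo) + (1 if self.n_sulfo else 0)

    @property
    def token(self) -> str:
        if self.ring.is_uronic:
            return self.ring.value + ("2S" if 2 in self.o_sulfo else "")
        tok = "GlcN" + self.n_sub.value
        if 3 in self.o_sulfo:
            tok += "3S"
        if 6 in self.o_sulfo:
            tok += "6S"
        return tok

    @classmethod
    def from_token(cls, token: str) -> "Residue":
        m = _URONIC_RE.match(token)
        if m:
            ring = Ring.GLUCO_URONIC if m.group(1) == "GlcA" else Ring.IDO_URONIC
            pos = frozenset({2}) if m.group(2) else frozenset()
            return cls(ring, NSub.NONE, pos)
        m = _AMINE_RE.match(token)
        if m:
            sub = {None: NSub.FREE_AMINE, "Ac": NSub.ACETYL,
                   "S": NSub.SULFO, "TFA": NSub.TFA}[m.group(1)]
            pos = set()
            if m.group(2):
                pos.add(3)
            if m.group(3):
                pos.add(6)
            return cls(Ring.GLUCOSAMINE, sub, frozenset(pos))
        raise GrammarError(f"unknown residue token {token!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


def _label(i: int) -> str:
    """Spreadsheet-style residue labels: A..Z, AA, AB, ..."""
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


@dataclass(frozen=True)
class Oligosaccharide:
    """An ordered (1->4)-linked chain; index 0 is the non-reducing end."""

    residues: tuple[Residue, ...]
    aglycone: Aglycone = Aglycone.FREE

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        if len(self.residues) < 1:
            raise ValidationError("an oligosaccharide needs at least one residue")
        for i in range(len(self.residues) - 1):
            a, b = self.residues[i], self.residues[i + 1]
            if a.is_uronic == b.is_uronic:
                kind = "uronic" if a.is_uronic else "glucosamine"
                raise ValidationError(
                    f"alternation violation: adjacent {kind} residues at "
                    f"positions {i} and {i + 1} "
                    f"({a.token!r}, {b.token!r})")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def labels(self) -> tuple[str, ...]:
        """Letters A, B, C, ... assigned from the non-reducing end."""
        return tuple(_label(i) for i in range(len(self.residues)))

    def residue(self, label: str) -> Residue:
        try:
            return self.residues[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"no residue labelled {label!r}") from None

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def replace(self, index: int, residue: Residue) -> "Oligosaccharide":
        res = list(self.residues)
        res[index] = residue
        return Oligosaccharide(tuple(res), self.aglycone)


_ARROWS = ("(1->4)", "(1→4)")


def parse_sequence(text: str) -> Oligosaccharide:
    """Parse a sequence string into a validated :class:`Oligosaccharide`.

    Raises :class:`GrammarError` for malformed text or unknown residue
    tokens and :class:`ValidationError` for chemically invalid chains
    (alternation violations, illegal sulfation).
    """
    s = text.strip()
    if not s:
        raise GrammarError("empty sequence string")
    for arrow in _ARROWS:
        s = s.replace(arrow, "(1-4)")
    aglycone = Aglycone.FREE
    for agl in (Aglycone.PNA_N3, Aglycone.PNP):
        suffix = "-" + agl.value
        if s.endswith(suffix):
            aglycone = agl
            s = s[: -len(suffix)]
            break
    tokens = s.split("(1-4)")
    if any(not t for t in tokens):
        raise GrammarError(f"malformed sequence string {text!r}")
    residues = tuple(Residue.from_token(t.strip()) for t in tokens)
    return Oligosaccharide(residues, aglycone)


def format_sequence(oligo: Oligosaccharide) -> str:
    """Canonical string form; inverse of :func:`parse_sequence`."""
    s = "(1-4)".join(r.token for r in oligo.residues)
    if oligo.aglycone is not Aglycone.FREE:
        s += "-" + oligo.aglycone.value
    return s


# The antithrombin III binding pentasaccharide, non-reducing -> reducing.
AT_MOTIF: tuple[str, ...] = (
    "GlcNS6S", "GlcA", "GlcNS3S6S", "IdoA2S", "GlcNS6S")


@dataclass(frozen=True)
class MotifHit:
    """A 5-residue window matching the AT-binding pentasaccharide."""

    start_label: str
    end_label: str
    residue_tokens: tuple[str, ...]


def find_at_motif(oligo: Oligosaccharide) -> list[MotifHit]:
    """All (possibly overlapping) windows matching the AT pentasaccharide."""
    labels = oligo.labels
    tokens = [r.token for r in oligo.residues]
    hits = []
    k = len(AT_MOTIF)
    for i in range(len(tokens) - k + 1):
        window = tuple(tokens[i:i + k])
        if window == AT_MOTIF:
            hits.append(MotifHit(labels[i], labels[i + k - 1], window))
    return hits


@dataclass(frozen=True)
class SulfationStats:
    """Sulfation summary of a chain.

    ``sulfo_per_disaccharide`` is the total sulfo count divided by the
    number of disaccharide units (residue count / 2); heparin averages
    ~2.6 against ~0.6 for a typical HS.  ``pct_idoA_of_uronic`` is the
    IdoA-type share of uronic residues (80-90% in heparin, ~20% in HS).
    """

    n_sulfo: int
    o2_sulfo: int
    o3_sulfo: int
    o6_sulfo: int
    sulfo_per_disaccharide: float
    pct_idoA_of_uronic: float

    @property
    def total_sulfo(self) -> int:
        return self.n_sulfo + self.o2_sulfo + self.o3_sulfo + self.o6_sulfo


def sulfation_stats(oligo: Oligosaccharide) -> SulfationStats:
    n_s = sum(1 for r in oligo if r.n_sulfo)
    o2 = sum(1 for r in oligo if r.is_uronic and 2 in r.o_sulfo)
    o3 = sum(1 for r in oligo if not r.is_uronic and 3 in r.o_sulfo)
    o6 = sum(1 for r in oligo if not r.is_uronic and 6 in r.o_sulfo)
    total = n_s + o2 + o3 + o6
    uronic = [r for r in oligo if r.is_uronic]
    ido = sum(1 for r in uronic if r.ring is Ring.IDO_URONIC)
    return SulfationStats(
        n_sulfo=n_s,
        o2_sulfo=o2,
        o3_sulfo=o3,
        o6_sulfo=o6,
        sulfo_per_disaccharide=total / (len(oligo) / 2),
        pct_idoA_of_uronic=100.0 * ido / len(uronic) if uronic else 0.0,
    )
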