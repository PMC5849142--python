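"""Rule-based anomeric NMR shift prediction for HS/heparin chains.

The anomeric H1/C1 chemical shift of a residue in these polymers is
determined almost entirely by the residue's own identity and by the
residue attached to its *reducing* side (presumably steric interaction
across the glycosidic bond); the non-reducing neighbor has minimal
impact.  The predictor therefore resolves each residue to one row of a
(residue class, reducing-side context class) lookup table:

* glucosamine residues see a gluco-uronic (GlcA-type) or ido-uronic
  (IdoA-type) context, 2-O-sulfation of the neighbor ignored;
* uronic residues see a glucosamine context split only by whether the
  neighbor carries a 6-O-sulfo group (which perturbs GlcA H1 more than
  the neighbor's N-sulfo state does);
* the reducing-end residue sees the aglycone -- the aromatic pNA tag
  de-shields the attached GlcA H1 to 5.07 ppm.

Combinations absent from the table (e.g. GlcNAc with an IdoA-type
neighbor, which the library never produces) raise
:class:`UnresolvedContextError` rather than extrapolating.

The three-bond H1-H2 coupling reports the anomeric configuration:
equatorial-equatorial ~4 Hz for alpha-linked residues (glucosamines and
ido-uronic acids), axial-axial ~8 Hz for beta-linked gluco-uronic acids.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .glycans import Aglycone, Oligosaccharide, Residue, Ring

J_ALPHA_HZ = 4.0
J_BETA_HZ = 8.0


class UnresolvedContextError(LookupError):
    """A residue/context pair has no row in the shift model."""

    def __init__(self, missing: list[tuple[str, str, str]]):
        self.missing = missing  # (label, residue token, context)
        pairs = ", ".join(f"{lab}: {res}|{ctx}" for lab, res, ctx in missing)
        super().__init__(f"no shift-model row for: {pairs}")


@dataclass(frozen=True)
class ShiftEntry:
    """One row of the shift model."""

    residue: str
    context: str
    delta_h: float
    tol_h: float
    delta_c: float | None
    tol_c: float | None
    note: str = ""


@dataclass(frozen=True)
class ShiftTable:
    version: str
    entries: tuple[ShiftEntry, ...]

    def lookup(self, residue: str, context: str) -> ShiftEntry | None:
        for e in self.entries:
            if e.residue == residue and e.context == context:
                return e
        return None


def _parse_table(text: str, version: str = "unversioned") -> ShiftTable:
    lines = []
    for raw in text.splitlines():
        if raw.startswith("# version:"):
            version = raw.split(":", 1)[1].strip()
        if raw.startswith("#") or not raw.strip():
            continue
        lines.append(raw)
    reader = csv.DictReader(_io.StringIO("\n".join(lines)), delimiter="\t")
    entries = []
    for row in reader:
        entries.append(ShiftEntry(
            residue=row["residue"],
            context=row["context"],
            delta_h=float(row["delta_h"]),
            tol_h=float(row["tol_h"]),
            delta_c=float(row["delta_c"]) if row.get("delta_c") else None,
            tol_c=float(row["tol_c"]) if row.get("tol_c") else None,
            note=(row.get("note") or "").strip(),
        ))
    return ShiftTable(version, tuple(entries))


@lru_cache(maxsize=1)
def default_shift_table() -> ShiftTable:
    text = (resources.files("heparlib") / "data" / "shift_table.tsv").read_text()
    return _parse_table(text)


def load_shift_table(path: str | Path) -> ShiftTable:
    """Load an override model table (same TSV layout as the packaged one)."""
    return _parse_table(Path(path).read_text())


def j_class(residue: Residue) -> float:
    """~4 Hz for alpha-linked residues, ~8 Hz for beta-linked GlcA-type."""
    return J_BETA_HZ if residue.anomeric_config == "beta" else J_ALPHA_HZ


def count_anomeric_signals(oligo: Oligosaccharide) -> int:
    """One anomeric proton per residue."""
    return len(oligo)


def context_of(oligo: Oligosaccharide, index: int) -> str:
    """Context class of residue ``index`` (its reducing-side neighbor)."""
    if index == len(oligo) - 1:
        return {Aglycone.PNA_N3: "pNA", Aglycone.PNP: "pNP",
                Aglycone.FREE: "free"}[oligo.aglycone]
    nb = oligo.residues[index + 1]
    if nb.ring is Ring.GLUCO_URONIC:
        return "GlcA"
    if nb.ring is Ring.IDO_URONIC:
        return "IdoA"
    return "GlcNX6S" if 6 in nb.o_sulfo else "GlcNX"


@dataclass(frozen=True)
class PredictedShift:
    """Prediction for one residue's anomeric position."""

    label: str
    residue: str
    context: str
    delta_h: float | None
    delta_c: float | None
    j_hz: float
    entry: ShiftEntry | None
    flags: tuple[str, ...] = ()


def predict_shifts(oligo: Oligosaccharide,
                   table: ShiftTable | None = None,
                   strict: bool = True) -> list[PredictedShift]:
    """Predict anomeric shifts for every residue of a chain.

    In strict mode an :class:`UnresolvedContextError` lists every
    residue/context pair missing from the model; with ``strict=False``
    unresolved residues get ``delta_h=None`` so the resolvable part of a
    chain can still be read off.
    """
    table = table or default_shift_table()
    out: list[PredictedShift] = []
    missing: list[tuple[str, str, str]] = []
    for i, (label, res) in enumerate(zip(oligo.labels, oligo.residues)):
        ctx = context_of(oligo, i)
        entry = table.lookup(res.token, ctx)
        if entry is None:
            missing.append((label, res.token, ctx))
            out.append(PredictedShift(label, res.token, ctx, None, None,
                                      j_class(res), None))
            continue
        flags = ("broad-IdoA2S",) if entry.note == "broad" else ()
        out.append(PredictedShift(label, res.token, ctx, entry.delta_h,
                                  entry.delta_c, j_class(res), entry, flags))
    if strict and missing:
        raise UnresolvedContextError(missing)
    return out


def anomeric_shift(residue_token: str, context: str,
                   table: ShiftTable | None = None) -> ShiftEntry:
    """Direct lookup of a (residue, context) model row."""
    table = table or default_shift_table()
    entry = table.lookup(residue_token, context)
    if entry is None:
        raise UnresolvedContextError([("-", residue_token, context)])
    return entry
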