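"""Synthetic anomeric peak lists and random valid sequences.

The simulator emulates the observed anomeric region of a 1D/2D spectrum
of a pure oligosaccharide: each residue emits one peak at its predicted
(H1, C1) position plus independent Gaussian noise, rows are shuffled
(peak order in a spectrum carries no residue information), and an
optional dropout removes a fraction of peaks, mimicking signals lost to
overlap or exchange broadening.  Default dispersions (sigma_H 0.02 ppm,
sigma_C 0.2 ppm) sit mid-range of the +/-0.02-0.04 ppm 1H and
+/-0.2-0.3 ppm 13C spreads observed across the library.  What the
simulator does *not* model -- lineshape, overlap, solvent and
temperature effects -- is discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assignment import Peak, PeakList
from .enzymes import PlannerConfig, enumerate_library
from .glycans import (Aglycone, Oligosaccharide, Residue, Ring,
                      ValidationError)
from .nmr import ShiftTable, predict_shifts

# Residue states occurring in finished library compounds (transient
# GlcNTFA / free-amine states excluded by default).
FINAL_URONIC = ("GlcA", "GlcA2S", "IdoA", "IdoA2S")
FINAL_AMINE = ("GlcNAc", "GlcNAc6S", "GlcNS", "GlcNS6S", "GlcNS3S6S")
TRANSIENT_AMINE = ("GlcNTFA", "GlcN")


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model for simulated anomeric peak lists."""

    noise_sigma_h: float = 0.02   # ppm
    noise_sigma_c: float = 0.2    # ppm
    rng_seed: int = 0
    n_replicates: int = 1
    dropout_rate: float = 0.0     # fraction of peaks omitted
    include_c: bool = True
    include_j: bool = False

    def __post_init__(self) -> None:
        if self.noise_sigma_h < 0 or self.noise_sigma_c < 0:
            raise ValueError("noise sigmas must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


def simulate_peaklist(oligo: Oligosaccharide, config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      table: ShiftTable | None = None
                      ) -> tuple[PeakList, dict[str, int | None]]:
    """One noisy peak list plus its ground-truth residue mapping.

    Returns ``(peaks, truth)`` where ``truth[label]`` is the row index of
    the peak emitted by that residue after shuffling, or ``None`` if the
    peak was dropped.  Identical seeds give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    preds = predict_shifts(oligo, table=table, strict=True)
    n = len(preds)
    order = rng.permutation(n)
    n_drop = int(round(config.dropout_rate * n))
    dropped = set(rng.choice(n, size=n_drop, replace=False)) if n_drop else set()

    truth: dict[str, int | None] = {}
    row_of_residue: dict[int, int] = {}
    for row_i, res_i in enumerate(i for i in order if i not in dropped):
        row_of_residue[res_i] = row_i
    for i, p in enumerate(preds):
        if i in dropped:
            truth[p.label] = None
            continue
        truth[p.label] = row_of_residue[i]
    # emit noise in residue order so dropout does not shift the stream
    noisy = []
    for p in preds:
        dh = p.delta_h + rng.normal(0.0, config.noise_sigma_h)
        dc = None
        if config.include_c and p.delta_c is not None:
            dc = p.delta_c + rng.normal(0.0, config.noise_sigma_c)
        noisy.append(Peak(dh, dc, p.j_hz if config.include_j else None))
    rows = [noisy[i] for i in order if i not in dropped]
    return PeakList(tuple(rows)), truth


def recovered(oligo: Oligosaccharide, assignment_pairs: dict,
              truth: dict, table: ShiftTable | None = None) -> bool:
    """Did an assignment recover the generating map?

    Residues with identical predicted rows (e.g. two GlcNS6S residues in
    the same context) are interchangeable, so recovery is judged up to
    exchange of residues whose predictions coincide.
    """
    preds = {p.label: (p.delta_h, p.delta_c, p.j_hz)
             for p in predict_shifts(oligo, table=table, strict=True)}
    true_label_of_row = {row: lab for lab, row in truth.items()
                         if row is not None}
    for label, row in assignment_pairs.items():
        if row is None:
            continue
        if row not in true_label_of_row:
            return False
        if preds[label] != preds[true_label_of_row[row]]:
            return False
    return True


def random_sequence(length: int, rng_seed: int | np.random.Generator = 0,
                    constraints: dict | None = None) -> Oligosaccharide:
    """A random valid alternating sequence.

    The reducing-end residue is uronic (as in the library, which grows
    from a GlcA-aglycone seed).  ``constraints`` may set ``aglycone``
    (default ``pNA-N3``), ``allow_transient`` (include GlcNTFA/GlcN
    states; default False) and ``reachable_only`` (draw uniformly from
    the enzyme-reachable states of that length; default False).
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    c = dict(constraints or {})
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    agl = c.get("aglycone", Aglycone.PNA_N3)
    aglycone = agl if isinstance(agl, Aglycone) else Aglycone(agl)
    if c.get("reachable_only"):
        seed = Oligosaccharide(
            (Residue(Ring.GLUCO_URONIC),), aglycone)
        depth = c.get("max_steps", 2 * length)
        pool = [o for o in enumerate_library(seed, depth,
                                             c.get("config", PlannerConfig()))
                if len(o) == length]
        if not pool:
            raise ValidationError(
                f"no enzyme-reachable sequence of length {length} within "
                f"{depth} steps")
        return pool[int(rng.integers(len(pool)))]
    amine_pool = FINAL_AMINE + (TRANSIENT_AMINE if c.get("allow_transient")
                                else ())
    tokens = []
    for k in range(length):
        # position length-1 (reducing end) is uronic; alternate backwards
        uronic = (length - 1 - k) % 2 == 0
        pool = FINAL_URONIC if uronic else amine_pool
        tokens.append(pool[int(rng.integers(len(pool)))])
    return Oligosaccharide(
        tuple(Residue.from_token(t) for t in tokens), aglycone)
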