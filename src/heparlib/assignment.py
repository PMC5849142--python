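"""Assign observed anomeric peaks to residues by cost-minimizing matching.

Formalizes the reasoning used when verifying a synthetic oligosaccharide
by NMR: each residue has a predicted anomeric (H1, C1, 3J_HH) signature,
and the observed anomeric peak list is matched to the residues by the
bijection (or injection, when peaks were lost to overlap/broadening)
minimizing the summed deviation

    cost(residue, peak) = |d(1H)| + w * |d(13C)| + J-mismatch penalty

with w = 0.1 per ppm by default (13C shift dispersions are roughly 10x
the 1H ones) and a flat 1.0 ppm-equivalent penalty for a coupling class
that contradicts the residue's anomeric configuration (an ~4 Hz peak on
a beta-linked GlcA-type residue is near-disqualifying).  Missing optional
peak dimensions contribute zero cost.

Instances up to 8 residues are solved by exhaustive enumeration with a
deterministic lexicographic tie-break in residue-label order; larger
instances use the optimal rectangular linear-assignment solver.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .glycans import Oligosaccharide, format_sequence
from .nmr import (J_ALPHA_HZ, J_BETA_HZ, PredictedShift, ShiftTable,
                  predict_shifts)

EXHAUSTIVE_MAX = 8


class AssignmentError(ValueError):
    """Peak list incompatible with the candidate sequence."""


@dataclass(frozen=True)
class Peak:
    """One observed anomeric signal (13C and J optional)."""

    delta_h: float
    delta_c: float | None = None
    j_hz: float | None = None

    def __post_init__(self) -> None:
        if not 3.0 <= self.delta_h <= 6.5:
            raise AssignmentError(
                f"anomeric 1H shift {self.delta_h} outside 3.0-6.5 ppm")


@dataclass(frozen=True)
class PeakList:
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class AssignmentConfig:
    c_weight: float = 0.1          # ppm-equivalents per ppm of 13C deviation
    j_penalty: float = 1.0         # flat penalty for a coupling-class clash
    default_tol_h: float = 0.05    # ppm, used when the model row prints none
    default_tol_c: float = 0.5     # ppm


def _pair_cost(pred: PredictedShift, peak: Peak,
               config: AssignmentConfig) -> float:
    cost = abs(peak.delta_h - pred.delta_h)
    if peak.delta_c is not None and pred.delta_c is not None:
        cost += config.c_weight * abs(peak.delta_c - pred.delta_c)
    if peak.j_hz is not None:
        peak_class = J_ALPHA_HZ if abs(peak.j_hz - J_ALPHA_HZ) < abs(
            peak.j_hz - J_BETA_HZ) else J_BETA_HZ
        if peak_class != pred.j_hz:
            cost += config.j_penalty
    return cost


@dataclass(frozen=True)
class Assignment:
    """Residue-label -> peak-index mapping with per-pair diagnostics."""

    pairs: dict = field(default_factory=dict)       # label -> peak index|None
    deviations: dict = field(default_factory=dict)  # label -> (dH, dC|None)
    total_cost: float = 0.0
    out_of_tolerance: tuple[str, ...] = ()
    unassigned_residues: tuple[str, ...] = ()


def _solve(cost: np.ndarray, n_res: int, n_peaks: int) -> list[int | None]:
    """Residue index -> peak index (None = unassigned). Optimal, deterministic."""
    if n_res <= EXHAUSTIVE_MAX:
        best_cost = None
        best: list[int | None] | None = None
        if n_peaks == n_res:
            # Lexicographic enumeration over residue->peak maps in label
            # order gives a deterministic tie-break (first optimum wins).
            for perm in itertools.permutations(range(n_peaks)):
                c = sum(cost[i, perm[i]] for i in range(n_res))
                if best_cost is None or c < best_cost - 1e-12:
                    best_cost, best = c, list(perm)
        else:
            # partial mode: choose which residues receive the peaks
            for positions in itertools.permutations(range(n_res), n_peaks):
                c = sum(cost[positions[k], k] for k in range(n_peaks))
                if best_cost is None or c < best_cost - 1e-12:
                    best_cost = c
                    assign: list[int | None] = [None] * n_res
                    for k, pos in enumerate(positions):
                        assign[pos] = k
                    best = assign
        return best
    # large instances: optimal rectangular linear assignment (peaks as rows
    # so every peak is assigned)
    rows, cols = linear_sum_assignment(cost.T)
    assign = [None] * n_res
    for peak_i, res_i in zip(rows, cols):
        assign[res_i] = int(peak_i)
    return assign


def assign_peaks(oligo: Oligosaccharide, peaks: PeakList,
                 config: AssignmentConfig | None = None,
                 table: ShiftTable | None = None) -> Assignment:
    """Optimal assignment of an anomeric peak list to a candidate sequence.

    Strict mode (peak count equal to residue count) returns a bijection;
    with fewer peaks the unmatched residues are reported unassigned.
    More peaks than residues is an error.
    """
    config = config or AssignmentConfig()
    preds = predict_shifts(oligo, table=table, strict=True)
    n_res, n_peaks = len(preds), len(peaks)
    if n_peaks > n_res:
        raise AssignmentError(
            f"{n_peaks} peaks cannot be assigned to {n_res} residues")
    if n_peaks == 0:
        raise AssignmentError("empty peak list")
    plist = list(peaks)
    cost = np.array([[_pair_cost(p, pk, config) for pk in plist]
                     for p in preds])
    assign = _solve(cost, n_res, n_peaks)
    pairs, deviations, flagged, unassigned = {}, {}, [], []
    total = 0.0
    for pred, peak_i in zip(preds, assign):
        pairs[pred.label] = peak_i
        if peak_i is None:
            unassigned.append(pred.label)
            continue
        pk = plist[peak_i]
        d_h = pk.delta_h - pred.delta_h
        d_c = (pk.delta_c - pred.delta_c
               if pk.delta_c is not None and pred.delta_c is not None else None)
        deviations[pred.label] = (d_h, d_c)
        total += _pair_cost(pred, pk, config)
        tol_h = pred.entry.tol_h if pred.entry else config.default_tol_h
        tol_c = (pred.entry.tol_c if pred.entry and pred.entry.tol_c
                 else config.default_tol_c)
        if abs(d_h) > tol_h or (d_c is not None and abs(d_c) > tol_c):
            flagged.append(pred.label)
    return Assignment(pairs=pairs, deviations=deviations, total_cost=total,
                      out_of_tolerance=tuple(flagged),
                      unassigned_residues=tuple(unassigned))


def score_candidates(peaks: PeakList, candidates: list[Oligosaccharide],
                     config: AssignmentConfig | None = None,
                     table: ShiftTable | None = None
                     ) -> list[tuple[Oligosaccharide, float]]:
    """Rank candidate sequences by optimal assignment cost (ascending).

    Ties are broken deterministically by the canonical sequence string.
    """
    if not candidates:
        raise AssignmentError("empty candidate list")
    scored = []
    for cand in candidates:
        a = assign_peaks(cand, peaks, config=config, table=table)
        scored.append((cand, a.total_cost))
    scored.sort(key=lambda t: (t[1], format_sequence(t[0])))
    return scored
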