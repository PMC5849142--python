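"""Chemoenzymatic route planning with enzyme substrate-specificity rules.

Encodes the enzymes of the chemoenzymatic HS/heparin synthesis platform
as transition operators on :class:`~heparlib.glycans.Oligosaccharide`
states, and searches for routes from a seed acceptor (typically the
GlcA-pNA-N3 monosaccharide) to a target structure.

Actions and their eligibility rules:

* ``pmHS2+GlcNAc`` / ``pmHS2+GlcNTFA`` -- heparosan synthase-2 elongates
  the non-reducing terminus with a glucosamine donor; requires a uronic
  terminus.
* ``pmHS2+GlcA`` -- elongation with GlcA; requires a glucosamine terminus.
* ``deTFA+NST`` -- mild alkaline de-N-trifluoroacetylation followed by
  N-sulfotransferase; converts every GlcNTFA to GlcNS in one atomic step
  (the two chemical operations are always paired in practice).
* ``C5-epi`` -- C5-epimerase; acts only on an unsulfated uronic residue
  flanked on both sides by N-sulfoglucosamines, and is modeled as a
  committed global toggle GlcA <-> IdoA (the enzyme is bidirectional;
  the equilibrium mixture itself is not modeled).
* ``C5-epi+2-OST`` -- the coupled epimerase/2-O-sulfotransferase step
  that traps the ido form as IdoA2S, which no enzyme can revert.
* ``2-OST-on-GlcA`` -- the slow direct 2-O-sulfation of GlcA (no
  epimerisation), producing the rare GlcA2S residue; the eligible site
  set is a configurable policy because the observed regiochemistry does
  not pin it down (see docs/methods.md).
* ``6-OST`` -- 6-O-sulfotransferases (isoforms merged); sulfates every
  GlcNS/GlcNAc lacking a 6-O-sulfo group.
* ``3-OST-1`` -- 3-O-sulfotransferase-1; site-selective for a GlcNS(6S)
  whose non-reducing neighbor is a gluco-uronic residue, preferring an
  IdoA2S on the reducing side when several positions qualify, and (by
  default) requiring the acceptor to already carry the 6-O-sulfo group.

Route search is breadth-first over canonicalized states with a
dominance prune: chains only grow and sulfo groups are never removed, so
any state that cannot be converted residue-by-residue (aligned from the
reducing end) into the target is discarded.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

from .glycans import (Aglycone, NSub, Oligosaccharide, Residue, Ring,
                      format_sequence)


class PlannerError(ValueError):
    pass


@dataclass(frozen=True)
class PlannerConfig:
    """Rule flags and search bounds.

    ``require_6s_for_3ost``: whether 3-OST-1 demands a 6-O-sulfated
    acceptor (every observed use acts on GlcNS6S; default on).
    ``two_ost_site_policy``: which GlcA residues direct 2-O-sulfation can
    reach -- ``internal`` (flanked by GlcNS on both sides),
    ``non_reducing`` (additionally the non-reducing terminus next to a
    GlcNS; the default, needed to place two GlcA2S on a pentasaccharide),
    or ``all`` (also the aglycone-bearing reducing terminus).
    """

    require_6s_for_3ost: bool = True
    two_ost_site_policy: str = "non_reducing"  # internal | non_reducing | all
    max_depth: int = 20


DEFAULT_CONFIG = PlannerConfig()


@dataclass(frozen=True)
class EnzymeAction:
    name: str
    donor: str | None          # UDP-sugar or PAPS cofactor
    mode: str                  # "elongate" | "global" | "site"
    adds_residue: str | None = None


ACTIONS: dict[str, EnzymeAction] = {a.name: a for a in (
    EnzymeAction("pmHS2+GlcNAc", "UDP-GlcNAc", "elongate", "GlcNAc"),
    EnzymeAction("pmHS2+GlcNTFA", "UDP-GlcNTFA", "elongate", "GlcNTFA"),
    EnzymeAction("pmHS2+GlcA", "UDP-GlcA", "elongate", "GlcA"),
    EnzymeAction("deTFA+NST", "PAPS", "global"),
    EnzymeAction("C5-epi", None, "global"),
    EnzymeAction("C5-epi+2-OST", "PAPS", "site"),
    EnzymeAction("2-OST-on-GlcA", "PAPS", "site"),
    EnzymeAction("6-OST", "PAPS", "global"),
    EnzymeAction("3-OST-1", "PAPS", "site"),
)}
ACTION_ORDER = tuple(ACTIONS)


def _ns_class(r: Residue) -> bool:
    """GlcNS, GlcNS6S and GlcNS3S6S all count as N-sulfoglucosamine."""
    return r.ring is Ring.GLUCOSAMINE and r.n_sub is NSub.SULFO


def _epi_flank(r: Residue) -> bool:
    """Flank requirement for the C5-epimerase site.

    N-sulfation of both flanking glucosamines is the determinant; a
    6-O-sulfo group on the flank is tolerated, but a 3-O-sulfo group
    blocks the enzyme (3-O-sulfation is the last biosynthetic step and
    its product is never epimerized next to).
    """
    return _ns_class(r) and 3 not in r.o_sulfo


def _epi_site(oligo: Oligosaccharide, i: int) -> bool:
    r = oligo.residues[i]
    if not (r.is_uronic and not r.o_sulfo):
        return False
    if i == 0 or i == len(oligo) - 1:
        return False
    return (_epi_flank(oligo.residues[i - 1])
            and _epi_flank(oligo.residues[i + 1]))


def eligible_sites(oligo: Oligosaccharide, action: str | EnzymeAction,
                   config: PlannerConfig = DEFAULT_CONFIG) -> list[str]:
    """Residue labels an action may act on (empty list = inapplicable)."""
    name = action.name if isinstance(action, EnzymeAction) else action
    if name not in ACTIONS:
        raise PlannerError(f"unknown action {name!r}")
    res = oligo.residues
    labels = oligo.labels
    n = len(res)

    if name in ("pmHS2+GlcNAc", "pmHS2+GlcNTFA"):
        return [labels[0]] if res[0].is_uronic else []
    if name == "pmHS2+GlcA":
        return [] if res[0].is_uronic else [labels[0]]
    if name == "deTFA+NST":
        return [labels[i] for i in range(n) if res[i].n_sub is NSub.TFA]
    if name in ("C5-epi", "C5-epi+2-OST"):
        return [labels[i] for i in range(n) if _epi_site(oligo, i)]
    if name == "2-OST-on-GlcA":
        out = []
        for i in range(n):
            r = res[i]
            if r.ring is not Ring.GLUCO_URONIC or 2 in r.o_sulfo:
                continue
            internal = (0 < i < n - 1 and _ns_class(res[i - 1])
                        and _ns_class(res[i + 1]))
            at_nr_end = i == 0 and n > 1 and _ns_class(res[1])
            at_red_end = i == n - 1 and n > 1 and _ns_class(res[i - 1])
            ok = {"internal": internal,
                  "non_reducing": internal or at_nr_end,
                  "all": internal or at_nr_end or at_red_end,
                  }[config.two_ost_site_policy]
            if ok:
                out.append(labels[i])
        return out
    if name == "6-OST":
        return [labels[i] for i in range(n)
                if res[i].ring is Ring.GLUCOSAMINE
                and res[i].n_sub in (NSub.SULFO, NSub.ACETYL)
                and 6 not in res[i].o_sulfo]
    if name == "3-OST-1":
        cand = []
        for i in range(n):
            r = res[i]
            if not _ns_class(r) or 3 in r.o_sulfo:
                continue
            if config.require_6s_for_3ost and 6 not in r.o_sulfo:
                continue
            if i == 0 or res[i - 1].ring is not Ring.GLUCO_URONIC:
                continue
            cand.append(i)
        if len(cand) > 1:
            preferred = [i for i in cand
                         if i < n - 1 and res[i + 1].ring is Ring.IDO_URONIC
                         and 2 in res[i + 1].o_sulfo]
            if preferred:
                cand = preferred
        return [labels[i] for i in cand]
    raise AssertionError(name)


def apply_action(oligo: Oligosaccharide, action: str | EnzymeAction,
                 sites: list[str] | tuple[str, ...] | None = None,
                 config: PlannerConfig = DEFAULT_CONFIG) -> Oligosaccharide:
    """Apply an enzyme action, checking site eligibility.

    Global and elongation actions act on the full eligible set (``sites``,
    if given, must equal it).  Site-selective actions default to the
    eligible set only when it is unambiguous (a single site).
    """
    name = action.name if isinstance(action, EnzymeAction) else action
    act = ACTIONS.get(name)
    if act is None:
        raise PlannerError(f"unknown action {name!r}")
    eligible = eligible_sites(oligo, name, config)
    if not eligible:
        raise PlannerError(f"{name} is not applicable to "
                           f"{format_sequence(oligo)}")
    if act.mode in ("global", "elongate"):
        if sites is not None and sorted(sites) != sorted(eligible):
            raise PlannerError(f"{name} acts globally on {eligible}")
        sites = eligible
    else:
        if sites is None:
            if len(eligible) != 1:
                raise PlannerError(
                    f"{name} is ambiguous here (eligible: {eligible}); "
                    "specify sites")
            sites = eligible
        elif not set(sites) <= set(eligible):
            bad = sorted(set(sites) - set(eligible))
            raise PlannerError(f"sites {bad} not eligible for {name} "
                               f"(eligible: {eligible})")

    if act.mode == "elongate":
        new = Residue.from_token(act.adds_residue)
        return Oligosaccharide((new,) + oligo.residues, oligo.aglycone)

    out = oligo
    for label in sites:
        i = out.index_of(label)
        r = out.residues[i]
        if name == "deTFA+NST":
            r = replace(r, n_sub=NSub.SULFO)
        elif name == "C5-epi":
            flipped = (Ring.IDO_URONIC if r.ring is Ring.GLUCO_URONIC
                       else Ring.GLUCO_URONIC)
            r = replace(r, ring=flipped)
        elif name == "C5-epi+2-OST":
            r = Residue(Ring.IDO_URONIC, NSub.NONE, frozenset({2}))
        elif name == "2-OST-on-GlcA":
            r = replace(r, o_sulfo=r.o_sulfo | {2})
        elif name == "6-OST":
            r = replace(r, o_sulfo=r.o_sulfo | {6})
        elif name == "3-OST-1":
            r = replace(r, o_sulfo=r.o_sulfo | {3})
        out = out.replace(i, r)
    return out


@dataclass(frozen=True)
class RouteStep:
    action: str
    sites: tuple[str, ...]

    @property
    def donor(self) -> str | None:
        return ACTIONS[self.action].donor


@dataclass(frozen=True)
class Route:
    start: Oligosaccharide
    steps: tuple[RouteStep, ...]
    end: Oligosaccharide

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def action_names(self) -> tuple[str, ...]:
        return tuple(s.action for s in self.steps)


@dataclass(frozen=True)
class InfeasibilityReport:
    start: str
    target: str
    max_depth: int
    states_explored: int
    reason: str


def validate_route(route: Route,
                   config: PlannerConfig = DEFAULT_CONFIG
                   ) -> tuple[bool, str | None]:
    """Replay a route, checking eligibility at every state.

    Returns ``(True, None)`` or ``(False, diagnostic)`` describing the
    first failing step.
    """
    state = route.start
    for k, step in enumerate(route.steps):
        try:
            state = apply_action(state, step.action, list(step.sites), config)
        except PlannerError as exc:
            return False, f"step {k + 1} ({step.action}): {exc}"
    if state != route.end:
        return False, (f"replay ends at {format_sequence(state)}, not "
                       f"{format_sequence(route.end)}")
    return True, None


# ---------------------------------------------------------------------------
# search

def _residue_compatible(a: Residue, b: Residue) -> bool:
    """Can residue state ``a`` still become ``b`` under some action sequence?

    Necessary (context-free) condition used for pruning: sulfo groups are
    never removed, 2-O-sulfated uronic acids are locked (IdoA2S cannot be
    epimerized back, GlcA2S is never epimerized), unsulfated uronic acids
    interconvert, GlcNTFA only ever becomes GlcNS, and N-acetyl /
    free-amine states are terminal apart from 6-O-sulfation of GlcNAc.
    """
    if a.is_uronic != b.is_uronic:
        return False
    if a.is_uronic:
        if 2 in a.o_sulfo:
            return a == b
        return True
    # glucosamine
    if not a.o_sulfo <= b.o_sulfo:
        return False
    if a.n_sub is NSub.TFA:
        if b.n_sub is NSub.TFA:
            return a.o_sulfo == b.o_sulfo
        return b.n_sub is NSub.SULFO
    if a.n_sub is NSub.ACETYL:
        return b.n_sub is NSub.ACETYL and b.o_sulfo - a.o_sulfo <= {6}
    if a.n_sub is NSub.FREE_AMINE:
        return a == b
    return b.n_sub is NSub.SULFO


def _compatible(state: Oligosaccharide, target: Oligosaccharide) -> bool:
    if state.aglycone is not target.aglycone:
        return False
    if len(state) > len(target):
        return False
    # elongation happens at the non-reducing end, so align from the
    # reducing end
    sr = state.residues[::-1]
    tr = target.residues[::-1]
    return all(_residue_compatible(a, b) for a, b in zip(sr, tr))


def _successors(state: Oligosaccharide, config: PlannerConfig):
    """Deterministically ordered (RouteStep, new state) pairs."""
    for name in ACTION_ORDER:
        act = ACTIONS[name]
        eligible = eligible_sites(state, name, config)
        if not eligible:
            continue
        if act.mode in ("global", "elongate"):
            yield (RouteStep(name, tuple(eligible)),
                   apply_action(state, name, eligible, config))
        else:
            for site in eligible:
                yield (RouteStep(name, (site,)),
                       apply_action(state, name, [site], config))
            if len(eligible) > 1:
                yield (RouteStep(name, tuple(eligible)),
                       apply_action(state, name, eligible, config))


def plan_route(seed: Oligosaccharide, target: Oligosaccharide,
               config: PlannerConfig = DEFAULT_CONFIG
               ) -> Route | InfeasibilityReport:
    """Shortest enzymatic route (by step count) from seed to target.

    Breadth-first search over states, deduplicated by canonical sequence
    string; ties between equal-length routes resolve deterministically by
    the fixed action ordering.  Returns an :class:`InfeasibilityReport`
    when no route exists within ``config.max_depth`` steps.
    """
    start_key = format_sequence(seed)
    target_key = format_sequence(target)
    if start_key == target_key:
        return Route(seed, (), target)
    explored = 0
    if not _compatible(seed, target):
        return InfeasibilityReport(
            start_key, target_key, config.max_depth, 0,
            "seed cannot be transformed into the target "
            "(incompatible residue states)")
    queue = deque([(seed, 0)])
    parents: dict[str, tuple[str, RouteStep] | None] = {start_key: None}
    while queue:
        state, depth = queue.popleft()
        if depth >= config.max_depth:
            continue
        explored += 1
        key = format_sequence(state)
        for step, new in _successors(state, config):
            new_key = format_sequence(new)
            if new_key in parents or not _compatible(new, target):
                continue
            parents[new_key] = (key, step)
            if new_key == target_key:
                steps = []
                k = new_key
                while parents[k] is not None:
                    pk, st = parents[k]
                    steps.append(st)
                    k = pk
                return Route(seed, tuple(reversed(steps)), new)
            queue.append((new, depth + 1))
    return InfeasibilityReport(
        start_key, target_key, config.max_depth, explored,
        f"no route within {config.max_depth} steps")


def enumerate_library(seed: Oligosaccharide, max_steps: int,
                      config: PlannerConfig = DEFAULT_CONFIG
                      ) -> list[Oligosaccharide]:
    """All distinct states reachable from the seed within ``max_steps``.

    Deterministic: breadth-first discovery order under the fixed action
    ordering; includes the seed itself.
    """
    if max_steps < 0:
        raise PlannerError("max_steps must be >= 0")
    seen = {format_sequence(seed)}
    out = [seed]
    frontier = [seed]
    for _ in range(max_steps):
        nxt = []
        for state in frontier:
            for _step, new in _successors(state, config):
                key = format_sequence(new)
                if key not in seen:
                    seen.add(key)
                    out.append(new)
                    nxt.append(new)
        frontier = nxt
        if not frontier:
            break
    return out
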