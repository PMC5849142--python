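# Methods

This note records the models implemented in `heparlib`, the assumptions
behind them, and the choices made where the underlying chemistry or the
published record leaves the design open.

## Sequence model

Chains are stored non-reducing → reducing (index 0 = residue A), the
direction in which both elongation chemistry and NMR assignment
conventions run.  The (1→4) linkage is uniform in this polymer family
and is therefore not stored per bond; anomeric configuration is a
derived property of ring type (β for gluco-uronic, α for ido-uronic and
glucosamine), consistent with the observed ³J(H1,H2) partition (~8 Hz
vs ~4 Hz).  Validation enforces strict uronic/glucosamine alternation,
ring-legal O-sulfo positions (2-O on uronic acids; 3-O/6-O on
glucosamines) and the constraint that a 3-O-sulfated glucosamine must be
N-sulfated — no synthesis path produces GlcNAc3S, and the type system
refuses it outright.  Transient synthesis states (GlcNTFA, free-amine
GlcN) are first-class residues so that routes can be represented
mid-synthesis.

### Fixture reconstruction

The packaged compound table flags each structure `printed` (stated as a
string in the running text: seed, IV, V, VI, 14) or `reconstructed`
(inferred from the synthesis routes).  Reconstruction logic:

* **I** — pentasaccharide, both glucosamines N-acetylated (stated);
  **III** and **VII** are the trisaccharide and heptasaccharide all-GlcNS
  homologues bracketing the published size range.
* **II** — one GlcNAc, one GlcNS.  Which is which is not stated in
  text; we place GlcNS at position D, i.e. the GlcNTFA donor used for
  the first (reducing-side) elongation and GlcNAc for the second, which
  is the natural order when the N-sulfation is introduced by a single
  global deprotection/NST step at the end.
* **28 / 46** — obtained by replaying the stated route (elongate the
  IdoA2S pentasaccharide with GlcNTFA (+GlcA, +GlcNTFA for 46), deprotect
  + N-sulfate, 6-O-sulfate globally, then 3-OST-1), with the 3-O site
  chosen by the selectivity rule below.  Both contain the AT
  pentasaccharide motif, as required.
* **65 / 66** — direct 2-O-sulfation of the all-GlcA pentasaccharide
  gives a mono- and a di-GlcA2S product; the published record does not
  say which GlcA carries the sulfate in the mono product.  We place it
  on the internal GlcA (residue C, the canonical 2-OST site) and, for
  the di product, additionally on the non-reducing terminal GlcA.

## Mass model

Neutral free-acid convention (–SO₃H, –COOH): this is the convention
under which the calculated average mass of the reference hexasaccharide
(1900.6 Da, formula C₄₈H₇₃N₇O₅₆S₈) matches the ESI-MS deconvolution.
The monoisotopic mass of the same formula is 1899.1 Da, ~1.5 Da lower —
so the quoted calculated value is an average mass, and `mass_result`
reports both from a single elemental composition.  Compositions are
condensation sums: free monosaccharide formulas minus (n−1) waters, the
aglycone phenol condensed with loss of one further water
(pNA-N₃ = C₁₂H₁₆N₄O₂ as the free phenol).  Average atomic weights are
the IUPAC 2013 conventional values stored to 5 decimals; the element set
includes F for the transient N-trifluoroacetyl state.  Charge ladders
use m/z = (M − z·1.00794)/z; Na⁺/K⁺ adducts and in-source sulfate loss
are not modeled.  An independent per-residue increment table
(hand-derived from textbook formulas) is kept in the test suite as an
oracle; the two paths agree to < 0.01 Da across all fixtures and random
chains.

## Anomeric shift model

One lookup row per (residue class, reducing-side context class).  Only
the reducing-side neighbor enters the context because the non-reducing
neighbor has a minimal observed effect on the anomeric shift.  Context
classes: gluco-uronic neighbor (2-O-sulfation ignored), ido-uronic
neighbor (likewise — the source data group IdoA and IdoA2S), glucosamine
neighbor split only by 6-O-sulfation (which perturbs the GlcA anomeric
proton more than the neighbor's N-substituent does), and the aromatic
pNA aglycone (de-shields the attached GlcA H1 to 5.07 ppm).  Treating
GlcA and GlcA2S neighbors as one class mirrors the IdoA(±2S) grouping
and is needed to predict glucosamines adjacent to the rare GlcA2S; it is
the model's only extrapolation beyond directly measured contexts.

Missing ¹³C values (GlcA before a 6-O-sulfated amine; the
aglycone-linked GlcA) are represented as absent and never imputed.
Residue/context combinations that the library never produced (e.g.
GlcNAc with an ido-uronic neighbor) raise an unresolved-context error
rather than guessing.  Default tolerances where none are recorded:
±0.05 ppm ¹H, ±0.5 ppm ¹³C — wide enough to cover the known
prediction/observation gap of 0.02 ppm for the 4.54-ppm GlcA row.  The
table ships as a versioned TSV and can be overridden per run.

## Peak assignment

Cost per pair: |ΔδH| + w·|ΔδC| + J penalty, with w = 0.1 per ppm
(¹³C dispersions run ~10× the ¹H ones, so this weights the two
dimensions comparably) and a flat 1.0 ppm-equivalent penalty when the
observed coupling class (nearer 4 Hz or 8 Hz) contradicts the residue's
anomeric configuration — effectively disqualifying unless everything
else is hopeless.  Missing optional dimensions contribute zero cost:
absence of evidence is not penalized.  Instances with ≤ 8 residues are
solved by exhaustive enumeration in lexicographic residue-label order
(deterministic tie-break); larger ones by the Hungarian algorithm, which
the test suite uses as an independent optimum check on the exhaustive
path.  Partial mode (fewer peaks than residues, as when individual
values inside a crowded 5.4–5.6 ppm region are unresolved) assigns every
peak and reports the unmatched residues.

## Enzyme rules and route search

* Elongation (pmHS2 with UDP-GlcNAc / UDP-GlcNTFA / UDP-GlcA) extends
  only the non-reducing terminus and must alternate ring types.
* De-N-trifluoroacetylation + NST is one atomic action GlcNTFA → GlcNS
  (the two chemical steps are always paired).
* C5-epimerase acts on an unsulfated uronic residue flanked by two
  N-sulfoglucosamines; a 6-O-sulfo on the flank is tolerated, a 3-O-sulfo
  blocks the enzyme (3-O-sulfation is the last biosynthetic step).  The
  enzyme is bidirectional; we model it as a committed global toggle
  GlcA ↔ IdoA rather than an equilibrium mixture, with the search's
  visited set absorbing the resulting cycles.  The coupled
  C5-epi + 2-OST action traps the ido form as IdoA2S, which no modeled
  action can revert; symmetrically GlcA2S is never epimerized.  This is
  the "lock" invariant the tests verify over the full reachable state
  space to depth 12 (9,478 states, < 2 s).
* 6-OST (isoforms merged, since they are used jointly with no recorded
  site split) sulfates every GlcNS/GlcNAc lacking 6-O-sulfo in one step.
* 3-OST-1 requires a gluco-uronic residue on the acceptor's non-reducing
  side; when several glucosamines qualify, an IdoA2S on the reducing
  side marks the preferred site (this uniquely selects the observed site
  in the hexa-, hepta- and octasaccharide products).  Whether a 6-O-sulfo
  group must already be present is a config flag, default on — every
  recorded use acts on GlcNS6S.
* Direct 2-O-sulfation of GlcA: eligible sites default to internal GlcA
  flanked by GlcNS plus the non-reducing terminal GlcA next to a GlcNS;
  the aglycone-bearing reducing-end GlcA is excluded unless enabled.
  The wider-than-internal default is required for the observed
  di-GlcA2S pentasaccharide to be makeable at all; the reducing-end
  exclusion reflects the steric/electronic difference of the
  tag-bearing residue and the absence of any observed product sulfated
  there.

Route planning is breadth-first search over canonical sequence strings
with a fixed action ordering (elongations before modifications), so
shortest routes are found and ties resolve deterministically; this
reproduces the published step sequences for the key intermediates and
the reference hexasaccharide exactly.  Site-selective actions branch
over each single eligible site plus the full eligible set (a one-step
multi-site application; arbitrary subsets are reachable as single-site
sequences).  A dominance prune discards states that cannot be converted
residue-by-residue into the target (chains never shrink, sulfo groups
are never removed, 2-O-sulfated uronic acids are locked), aligned from
the reducing end since growth happens at the other terminus; this makes
infeasibility reports fast instead of exhausting the depth bound.
Default depth bound: 20 steps.

## Synthetic data

The simulator emulates the anomeric region of a clean 1D/HSQC spectrum:
one peak per residue at the model position plus independent Gaussian
noise, rows shuffled, optional dropout (count = round(rate × n)) for
signals lost to overlap or exchange broadening.  Default dispersions
σ_H = 0.02 ppm and σ_C = 0.2 ppm sit mid-range of the ±0.02–0.04 ppm /
±0.2–0.3 ppm spreads recorded across the library; the recorded ± values
are read as dispersion, not instrument uncertainty.  A single seeded
generator drives permutation, dropout and noise, so identical seeds give
identical lists.

Assignment *recovery* is judged up to exchange of residues with
identical predicted rows: in the reference hexasaccharide residues A and
E share 5.52/97.1/4 Hz exactly, so no assignment method can (or needs
to) tell them apart; the relevant resolution scale is the 0.09 ppm
minimum separation between *distinct* predicted shifts.  Monte-Carlo
tests (200 replicates) confirm ≥ 99% recovery at σ_H = 0.01 ppm, i.e.
whenever distinct-shift separations exceed 4σ.

What the simulator does **not** model — lineshape and linewidth (the
broad IdoA2S signal is only flagged, not broadened), peak overlap,
solvent/temperature/cation effects, ¹³C satellite structure — means
passing these tests demonstrates the correctness of the matching
machinery under the stated noise model, not robustness to every
pathology of real spectra.

## Problem sizes and determinism

The test suite runs at the library's natural scales: chains of 1–13
residues, exhaustive matching up to 8! bijections, state enumeration to
depth 12 (9,478 states), 200-replicate Monte-Carlo batches.  The whole
suite completes in a few seconds.  All randomness flows through
explicitly seeded NumPy generators; CLI runs log the shift-model version
and configuration used.

## Known limitations

* The shift model covers exactly the measured residue/context rows plus
  the one documented GlcA≈GlcA2S context merge; sequences containing
  other unmeasured combinations (including pNP- or free-reducing-end
  chains beyond GlcA-pNA) require a user-supplied table.
* Reconstructed fixtures (II, III, VII, 28, 46, 65, 66) encode one
  defensible reading of the route logic; alternatives (e.g. the mirror
  placement in II, a terminal 2-O site in 65) are representable but not
  shipped.
* The planner optimizes step count only — no yields, kinetics, donor
  stoichiometry or purification cost.
* Mass logic excludes adducts, in-source SO₃ loss and isotope patterns;
  it predicts neutral masses and ideal [M − zH]^z− positions only.
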