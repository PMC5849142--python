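# heparlib

Sequence, mass-spectrometry, NMR and route-planning tools for
chemoenzymatically synthesized heparan sulfate (HS) and heparin
oligosaccharides.

## Who this is for

Heparin is a linear sulfated glycosaminoglycan of alternating
(1→4)-linked uronic acid (β-D-GlcA or its C5 epimer α-L-IdoA) and
α-D-glucosamine residues, decorated with N-, 2-O-, 3-O- and 6-O-sulfo
groups.  Structurally defined oligosaccharide standards for this polymer
are made by chemoenzymatic synthesis: a UV-tagged GlcA monosaccharide
acceptor is elongated by the heparosan synthase pmHS2 from UDP-sugar
donors, then modified by N-/O-sulfotransferases (NST, 2-OST, 6-OST,
3-OST-1) and C5-epimerase, whose substrate specificities dictate which
structures are reachable and in which order the steps must run.  Each
product is verified by negative-mode ESI-MS and by its anomeric
¹H/¹³C NMR signature.

`heparlib` packages the computational side of that workflow for
synthesis planners and heparin QC analysts:

* **Sequence model** — a text grammar for HS/heparin chains
  (`GlcNS6S(1-4)GlcA(1-4)...-pNA-N3`), validation of the alternation and
  sulfation rules, sulfation statistics, and a search for the
  antithrombin-binding pentasaccharide motif
  GlcNS6S–GlcA–GlcNS3S6S–IdoA2S–GlcNS6S.
* **Mass spec** — elemental composition, average/monoisotopic mass
  (neutral free-acid convention) and [M − zH]^z− ESI charge-state
  ladders.
* **NMR shift model** — a context-dependent predictor of anomeric
  ¹H/¹³C shifts: each residue's anomeric shift is looked up by (residue
  class, reducing-side neighbor class), plus the ~4 Hz (α) / ~8 Hz (β)
  ³J(H1,H2) coupling classes.
* **Peak assignment** — minimum-cost matching of an observed anomeric
  peak list onto a candidate sequence, cost
  `|ΔδH| + 0.1·|ΔδC| + J-mismatch penalty`, exhaustive for ≤ 8 residues
  and Hungarian otherwise; candidate ranking for QC.
* **Route planner** — the enzyme actions with their eligibility rules
  (e.g. C5-epimerase only attacks a GlcA flanked by two
  N-sulfoglucosamines; 3-OST-1 needs a GlcA on the acceptor's
  non-reducing side) and breadth-first search for shortest routes from
  the seed acceptor to a target, plus full library enumeration.
* **Simulator** — noisy synthetic anomeric peak lists with ground truth,
  for validating the assignment machinery.

## Worked example

The reference hexasaccharide (library compound 14) is
`GlcNS6S(1-4)GlcA(1-4)GlcNS3S6S(1-4)IdoA2S(1-4)GlcNS6S(1-4)GlcA-pNA-N3`,
where `pNA-N3` is the azide-bearing UV tag on the reducing end.

```
$ heparlib mass --seq "@14" --mono
sequence        formula         average_da  monoisotopic_da
GlcNS6S(1-4)... C48H73N7O56S8   1900.6      1899.1
```

The average mass 1900.6 Da is the value an ESI-MS deconvolution should
return for the neutral free acid (the observed value for this compound
was 1901.1 ± 0.8).  `heparlib mz --mass 1900.6 --charges 4,5,6` prints
the expected multiply charged ions m/z 474.14 / 379.11 / 315.76.

```
$ heparlib shifts --seq "@14"
label  residue    context  delta_h  delta_c  j_hz  flags
A      GlcNS6S    GlcA     5.52     97.10    4.0
B      GlcA       GlcNX6S  4.54              8.0
C      GlcNS3S6S  IdoA     5.43     96.00    4.0
D      IdoA2S     GlcNX6S  5.18     99.00    4.0   broad-IdoA2S
E      GlcNS6S    GlcA     5.52     97.10    4.0
F      GlcA       pNA      5.07              8.0
```

Six anomeric signals confirm a hexasaccharide.  Residue C shows the
diagnostic ~5.43 ppm downfield shift of a 3-O-sulfated glucosamine next
to IdoA2S; residue B's GlcA moves from 4.43 to 4.54 ppm because its
reducing-side glucosamine carries a 6-O-sulfo group; residue F's 5.07 ppm
reflects aromatic de-shielding by the tag; the IdoA2S signal is flagged
broad (ring conformer exchange).  Blank δC entries are unmeasured values
the model refuses to impute.  Matching the two observed β-anomeric peaks
(4.56, 5.07 ppm) onto this sequence assigns them to B and F:

```
$ printf 'ppm_h\n4.56\n5.07\n' > peaks.csv
$ heparlib assign --seq "@14" --peaks peaks.csv
label  peak  ppm_h  dev_h  flag
A
B      0     4.56   0.02
C
D
E
F      1     5.07   0.00
# total cost 0.0200
```

Route planning from the seed acceptor (`heparlib plan --target "@IV"`)
returns the five-step elongation/N-sulfation route to the all-GlcNS
pentasaccharide intermediate; `--target "@14"` appends the
epimerization/2-O-, 6-O-, 3-O-sulfation steps in the required order.
Fixture names (`@seed`, `@I`–`@VII`, `@14`, `@28`, `@46`, `@65`, `@66`)
may be used anywhere a sequence is accepted.

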