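# version: 1
# Context-dependent anomeric 1H/13C chemical shift model (D2O, 298 K).
# context = the residue on the REDUCING side of the predicted residue
# (or the aglycone for the reducing-end residue).  Context classes:
#   GlcA    gluco-uronic neighbor (2-O-sulfation ignored)
#   IdoA    ido-uronic neighbor (2-O-sulfation ignored)
#   GlcNX   glucosamine neighbor without 6-O-sulfo (X = Ac or SO3)
#   GlcNX6S glucosamine neighbor carrying 6-O-sulfo
#   pNA     the pNA-N3 aglycone (aromatic de-shielding context)
# Missing 13C entries are genuinely unmeasured and left blank, never
# imputed.  note=broad marks the conformationally exchange-broadened
# IdoA2S anomeric signal.
residue	context	delta_h	tol_h	delta_c	tol_c	note
GlcNS	GlcA	5.52	0.04	97.0	0.2
GlcNS	IdoA	5.24	0.02	97.3	0.2
GlcNS6S	GlcA	5.52	0.04	97.1	0.2
GlcNS6S	IdoA	5.33	0.02	96.2	0.2
GlcNS3S6S	IdoA	5.43	0.04	96.0	0.2
GlcNAc	GlcA	5.32	0.03	96.8	0.3
GlcNAc6S	GlcA	5.33	0.02	96.7	0.3
GlcA	GlcNX	4.43	0.05	102.0	0.5
GlcA	GlcNX6S	4.54	0.05
GlcA2S	GlcNX	4.65	0.05	100.1	0.5
IdoA	GlcNX	4.95	0.05	101.5	0.5
IdoA	GlcNX6S	4.95	0.05	101.5	0.5
IdoA2S	GlcNX	5.18	0.05	99.0	0.5	broad
IdoA2S	GlcNX6S	5.18	0.05	99.0	0.5	broad
GlcA	pNA	5.07	0.05
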