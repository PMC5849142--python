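# Named compounds of the chemoenzymatic HS/heparin library.
# flag "printed": structure stated in running text; "reconstructed":
# inferred from the synthesis-route logic (see docs/methods.md).
# name	sequence	flag
seed	GlcA-pNA-N3	printed
I	GlcA(1-4)GlcNAc(1-4)GlcA(1-4)GlcNAc(1-4)GlcA-pNA-N3	reconstructed
II	GlcA(1-4)GlcNAc(1-4)GlcA(1-4)GlcNS(1-4)GlcA-pNA-N3	reconstructed
III	GlcA(1-4)GlcNS(1-4)GlcA-pNA-N3	reconstructed
IV	GlcA(1-4)GlcNS(1-4)GlcA(1-4)GlcNS(1-4)GlcA-pNA-N3	printed
V	GlcA(1-4)GlcNS(1-4)IdoA(1-4)GlcNS(1-4)GlcA-pNA-N3	printed
VI	GlcA(1-4)GlcNS(1-4)IdoA2S(1-4)GlcNS(1-4)GlcA-pNA-N3	printed
VII	GlcA(1-4)GlcNS(1-4)GlcA(1-4)GlcNS(1-4)GlcA(1-4)GlcNS(1-4)GlcA-pNA-N3	reconstructed
14	GlcNS6S(1-4)GlcA(1-4)GlcNS3S6S(1-4)IdoA2S(1-4)GlcNS6S(1-4)GlcA-pNA-N3	printed
28	GlcA(1-4)GlcNS6S(1-4)GlcA(1-4)GlcNS3S6S(1-4)IdoA2S(1-4)GlcNS6S(1-4)GlcA-pNA-N3	reconstructed
46	GlcNS6S(1-4)GlcA(1-4)GlcNS6S(1-4)GlcA(1-4)GlcNS3S6S(1-4)IdoA2S(1-4)GlcNS6S(1-4)GlcA-pNA-N3	reconstructed
65	GlcA(1-4)GlcNS(1-4)GlcA2S(1-4)GlcNS(1-4)GlcA-pNA-N3	reconstructed
66	GlcA2S(1-4)GlcNS(1-4)GlcA2S(1-4)GlcNS(1-4)GlcA-pNA-N3	reconstructed
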