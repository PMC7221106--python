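Fos
Fosb
Jun
Junb
Jund
Egr1
Egr2
Ier2
Ier3
Atf3
Arc
Npas4
Nr4a1
Dusp1
Hspa1a
Hspa1b
Hspa8
Hsp90aa1
Hsp90ab1
Socs3
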