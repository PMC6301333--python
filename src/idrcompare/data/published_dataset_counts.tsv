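# Published per-dataset composition of the 2018 curated intrinsic-disorder
# snapshot (annotated proteins, merged regions, disordered residues), as
# reported by the source databases through MobiDB 3.0.
# dataset	proteins	regions	residues
DIBS	465	514	12770
DisProt	721	1087	81632
ELM	1772	2579	19325
FuzDB	99	140	8768
IDEAL	752	2783	47315
MFIB	246	253	22487
UniProt	406	424	38224
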