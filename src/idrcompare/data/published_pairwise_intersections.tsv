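# Published pairwise protein-accession intersections between curated
# intrinsic-disorder sources (2018 MobiDB 3.0 snapshot).
# dataset_a	dataset_b	shared_proteins
DisProt	DIBS	76
DisProt	IDEAL	92
DisProt	ELM	100
DIBS	IDEAL	153
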