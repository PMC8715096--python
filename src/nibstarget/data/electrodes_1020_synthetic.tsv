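# Synthetic idealized international 10-20 electrode positions in MNI mm.
# Left-right symmetric layout in the lineage of published standard-position
# tables; midline/frontal placements calibrated once against the scalp
# projection used by nibstarget.montage and then frozen.  Swappable via
# --electrodes; outputs record this file's checksum.
label	x	y	z
Fp1	-26	68	0
Fpz	0	72	2
Fp2	26	68	0
F7	-62	34	-10
F3	-46	44	28
Fz	0	58	36
F4	46	44	28
F8	62	34	-10
T3	-72	-22	-10
C3	-56	-16	56
Cz	0	4	76
C4	56	-16	56
T4	72	-22	-10
T5	-62	-64	2
P3	-38	-76	48
Pz	0	-62	64
P4	38	-76	48
T6	62	-64	2
O1	-26	-98	12
Oz	0	-102	14
O2	26	-98	12
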