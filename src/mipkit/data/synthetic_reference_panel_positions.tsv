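# SYNTHETIC panel position map (1-based; NPA_* index the N of the triplet)
id	subfamily	NPA_LB	NPA_LE	H2	H5	LE1	LE2	P1	P2	P3	P4	P5	SDP1	SDP2	SDP3	SDP4	SDP5	SDP6	SDP7	SDP8	SDP9
refNIP-1	NIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refNIP-2	NIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refNIP-3	NIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refPIP-1	PIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refPIP-2	PIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refPIP-3	PIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refSIP-1	SIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refSIP-2	SIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refSIP-3	SIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refTIP-1	TIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refTIP-2	TIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
refTIP-3	TIP	90	209	66	196	213	215	222	260	262	264	266	8	12	46	50	130	136	175	226	230
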