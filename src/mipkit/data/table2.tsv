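gene_id	NPA_LB	NPA_LE	H2	H5	LE1	LE2	P1	P2	P3	P4	P5
CaNIP1-1	NPA	NPA	W	V	A	R	F	S	A	Y	I
CaNIP1-2	NPA	NPA	W	L	A	R	F	S	A	Y	I
CaNIP1-3	NPA	NPA	W	V	A	R	F	S	A	Y	L
CaNIP1-4	NPA	NPA	W	V	A	R	F	S	A	Y	L
CaNIP1-5	NPA	NPA	W	A	A	R	F	S	A	Y	L
CaNIP1-6	NPA	NPA	W	V	A	R	F	S	A	Y	L
CaNIP1-7	NPA	NPA	W	V	A	R	F	S	A	Y	I
CaNIP1-8	NPA	NPA	W	V	A	R	F	S	A	Y	L
CaNIP1-9	NPA	NPA	W	I	A	R	F	S	A	Y	L
CaNIP2-1	NPA	NPA	G	S	G	R	L	T	A	Y	M
CaNIP3-1	NPA	NPV	S	I	G	R	F	S	A	Y	L
CaNIP3-2	NPA	NPV	S	I	G	R	F	A	A	Y	L
CaNIP3-3	NPA	-	S	I	-	-	F	-	-	-	-
CaNIP3-4	NPS	NPV	A	I	G	R	Y	T	A	Y	L
CaNIP4-1	NPA	NPA	A	V	G	R	Y	S	A	Y	I
CaNIP6-1	NPA	NPV	S	I	G	R	-	T	T	Y	L
CaPIP1-1	NPA	NPA	F	H	T	R	E	S	A	F	W
CaPIP1-2	NPA	NPA	F	H	T	R	E	S	A	F	W
CaPIP1-3	NPA	NPA	F	H	T	R	E	S	A	F	W
CaPIP1-4	NPA	NPA	F	H	T	R	E	S	A	F	W
CaPIP2-1	NPA	NPA	F	H	T	R	Q	S	A	F	W
CaPIP2-2	NPA	NPA	F	H	T	R	Q	S	A	F	W
CaPIP2-3	NPA	NPA	F	H	T	R	Q	S	A	F	W
CaPIP2-4	NPA	NPA	F	H	T	R	Q	S	A	Y	W
CaPIP2-5	NPA	NPA	F	H	T	R	M	S	A	F	W
CaSIP1-1	NPT	NPA	L	V	P	N	I	A	A	Y	W
CaSIP1-2	NPT	NPV	L	I	P	L	I	V	V	-	-
CaSIP2-1	NPL	NPA	F	H	G	A	I	V	A	Y	W
CaTIP1-1	NPA	NPA	H	I	A	V	T	S	A	Y	W
CaTIP1-2	NPA	NPA	H	I	A	V	T	S	A	Y	W
CaTIP1-3	NPA	NPA	H	I	A	V	T	S	A	Y	W
CaTIP1-4	NPA	NPA	H	I	A	V	T	S	A	Y	W
CaTIP2-1	NPA	NPA	H	I	G	R	T	S	A	Y	W
CaTIP2-2	NPA	NPA	H	I	G	R	T	S	A	Y	W
CaTIP2-3	NPA	NPA	H	I	G	R	T	S	A	Y	W
CaTIP3-1	NPA	NPA	H	I	A	R	T	A	A	Y	W
CaTIP3-2	NPA	NPA	H	I	A	L	T	A	S	F	W
CaTIP4-1	NPA	NPA	Q	I	A	R	S	S	A	Y	W
CaTIP4-2	NPA	NPA	H	I	A	R	S	S	A	Y	W
CaTIP5-1	NPA	NPA	N	V	G	C	L	A	A	Y	W
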