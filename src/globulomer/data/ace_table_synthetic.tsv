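# Synthetic 18-type atomic contact energy table (kcal/mol per contact).
# Stand-in constructed from a hydrophobicity scale: hydrophobic-hydrophobic pairs negative, polar/charged pairs positive;
# e(i,j) = (h_i + h_j)/2.  Not the published parameter set.
TYPES	NBB	CABB	CBB	OBB	CAGLY	CH2	CH3	CARO	CFUN	NAMD	NARO	NPOS	OCRB	OAMD	OHYD	SSUL	CRNG	CTHI
ENERGY	NBB	0.400
ENERGY	CABB	0.200	0.000
ENERGY	CBB	0.300	0.100	0.200
ENERGY	OBB	0.400	0.200	0.300	0.400
ENERGY	CAGLY	0.250	0.050	0.150	0.250	0.100
ENERGY	CH2	-0.025	-0.225	-0.125	-0.025	-0.175	-0.450
ENERGY	CH3	-0.125	-0.325	-0.225	-0.125	-0.275	-0.550	-0.650
ENERGY	CARO	-0.075	-0.275	-0.175	-0.075	-0.225	-0.500	-0.600	-0.550
ENERGY	CFUN	0.275	0.075	0.175	0.275	0.125	-0.150	-0.250	-0.200	0.150
ENERGY	NAMD	0.450	0.250	0.350	0.450	0.300	0.025	-0.075	-0.025	0.325	0.500
ENERGY	NARO	0.250	0.050	0.150	0.250	0.100	-0.175	-0.275	-0.225	0.125	0.300	0.100
ENERGY	NPOS	0.650	0.450	0.550	0.650	0.500	0.225	0.125	0.175	0.525	0.700	0.500	0.900
ENERGY	OCRB	0.675	0.475	0.575	0.675	0.525	0.250	0.150	0.200	0.550	0.725	0.525	0.925	0.950
ENERGY	OAMD	0.475	0.275	0.375	0.475	0.325	0.050	-0.050	0.000	0.350	0.525	0.325	0.725	0.750	0.550
ENERGY	OHYD	0.450	0.250	0.350	0.450	0.300	0.025	-0.075	-0.025	0.325	0.500	0.300	0.700	0.725	0.525	0.500
ENERGY	SSUL	-0.050	-0.250	-0.150	-0.050	-0.200	-0.475	-0.575	-0.525	-0.175	0.000	-0.200	0.200	0.225	0.025	0.000	-0.500
ENERGY	CRNG	0.025	-0.175	-0.075	0.025	-0.125	-0.400	-0.500	-0.450	-0.100	0.075	-0.125	0.275	0.300	0.100	0.075	-0.425	-0.350
ENERGY	CTHI	0.050	-0.150	-0.050	0.050	-0.100	-0.375	-0.475	-0.425	-0.075	0.100	-0.100	0.300	0.325	0.125	0.100	-0.400	-0.325	-0.300
ASSIGN	ALA	N	NBB
ASSIGN	ALA	CA	CABB
ASSIGN	ALA	C	CBB
ASSIGN	ALA	O	OBB
ASSIGN	ALA	CB	CH3
ASSIGN	ARG	N	NBB
ASSIGN	ARG	CA	CABB
ASSIGN	ARG	C	CBB
ASSIGN	ARG	O	OBB
ASSIGN	ARG	CB	CH2
ASSIGN	ARG	CG	CH2
ASSIGN	ARG	CD	CH2
ASSIGN	ARG	NE	NPOS
ASSIGN	ARG	CZ	CFUN
ASSIGN	ARG	NH1	NPOS
ASSIGN	ARG	NH2	NPOS
ASSIGN	ASN	N	NBB
ASSIGN	ASN	CA	CABB
ASSIGN	ASN	C	CBB
ASSIGN	ASN	O	OBB
ASSIGN	ASN	CB	CH2
ASSIGN	ASN	CG	CFUN
ASSIGN	ASN	OD1	OAMD
ASSIGN	ASN	ND2	NAMD
ASSIGN	ASP	N	NBB
ASSIGN	ASP	CA	CABB
ASSIGN	ASP	C	CBB
ASSIGN	ASP	O	OBB
ASSIGN	ASP	CB	CH2
ASSIGN	ASP	CG	CFUN
ASSIGN	ASP	OD1	OCRB
ASSIGN	ASP	OD2	OCRB
ASSIGN	CYS	N	NBB
ASSIGN	CYS	CA	CABB
ASSIGN	CYS	C	CBB
ASSIGN	CYS	O	OBB
ASSIGN	CYS	CB	CH2
ASSIGN	CYS	SG	SSUL
ASSIGN	GLN	N	NBB
ASSIGN	GLN	CA	CABB
ASSIGN	GLN	C	CBB
ASSIGN	GLN	O	OBB
ASSIGN	GLN	CB	CH2
ASSIGN	GLN	CG	CH2
ASSIGN	GLN	CD	CFUN
ASSIGN	GLN	OE1	OAMD
ASSIGN	GLN	NE2	NAMD
ASSIGN	GLU	N	NBB
ASSIGN	GLU	CA	CABB
ASSIGN	GLU	C	CBB
ASSIGN	GLU	O	OBB
ASSIGN	GLU	CB	CH2
ASSIGN	GLU	CG	CH2
ASSIGN	GLU	CD	CFUN
ASSIGN	GLU	OE1	OCRB
ASSIGN	GLU	OE2	OCRB
ASSIGN	GLY	N	NBB
ASSIGN	GLY	CA	CAGLY
ASSIGN	GLY	C	CBB
ASSIGN	GLY	O	OBB
ASSIGN	HIS	N	NBB
ASSIGN	HIS	CA	CABB
ASSIGN	HIS	C	CBB
ASSIGN	HIS	O	OBB
ASSIGN	HIS	CB	CH2
ASSIGN	HIS	CG	CTHI
ASSIGN	HIS	ND1	NARO
ASSIGN	HIS	CD2	CTHI
ASSIGN	HIS	CE1	CTHI
ASSIGN	HIS	NE2	NARO
ASSIGN	ILE	N	NBB
ASSIGN	ILE	CA	CABB
ASSIGN	ILE	C	CBB
ASSIGN	ILE	O	OBB
ASSIGN	ILE	CB	CH2
ASSIGN	ILE	CG1	CH2
ASSIGN	ILE	CG2	CH3
ASSIGN	ILE	CD1	CH3
ASSIGN	LEU	N	NBB
ASSIGN	LEU	CA	CABB
ASSIGN	LEU	C	CBB
ASSIGN	LEU	O	OBB
ASSIGN	LEU	CB	CH2
ASSIGN	LEU	CG	CH2
ASSIGN	LEU	CD1	CH3
ASSIGN	LEU	CD2	CH3
ASSIGN	LYS	N	NBB
ASSIGN	LYS	CA	CABB
ASSIGN	LYS	C	CBB
ASSIGN	LYS	O	OBB
ASSIGN	LYS	CB	CH2
ASSIGN	LYS	CG	CH2
ASSIGN	LYS	CD	CH2
ASSIGN	LYS	CE	CFUN
ASSIGN	LYS	NZ	NPOS
ASSIGN	MET	N	NBB
ASSIGN	MET	CA	CABB
ASSIGN	MET	C	CBB
ASSIGN	MET	O	OBB
ASSIGN	MET	CB	CH2
ASSIGN	MET	CG	CH2
ASSIGN	MET	SD	SSUL
ASSIGN	MET	CE	CH3
ASSIGN	PHE	N	NBB
ASSIGN	PHE	CA	CABB
ASSIGN	PHE	C	CBB
ASSIGN	PHE	O	OBB
ASSIGN	PHE	CB	CH2
ASSIGN	PHE	CG	CARO
ASSIGN	PHE	CD1	CARO
ASSIGN	PHE	CD2	CARO
ASSIGN	PHE	CE1	CARO
ASSIGN	PHE	CE2	CARO
ASSIGN	PHE	CZ	CARO
ASSIGN	PRO	N	NBB
ASSIGN	PRO	CA	CABB
ASSIGN	PRO	C	CBB
ASSIGN	PRO	O	OBB
ASSIGN	PRO	CB	CRNG
ASSIGN	PRO	CG	CRNG
ASSIGN	PRO	CD	CRNG
ASSIGN	SER	N	NBB
ASSIGN	SER	CA	CABB
ASSIGN	SER	C	CBB
ASSIGN	SER	O	OBB
ASSIGN	SER	CB	CH2
ASSIGN	SER	OG	OHYD
ASSIGN	THR	N	NBB
ASSIGN	THR	CA	CABB
ASSIGN	THR	C	CBB
ASSIGN	THR	O	OBB
ASSIGN	THR	CB	CH2
ASSIGN	THR	OG1	OHYD
ASSIGN	THR	CG2	CH3
ASSIGN	TRP	N	NBB
ASSIGN	TRP	CA	CABB
ASSIGN	TRP	C	CBB
ASSIGN	TRP	O	OBB
ASSIGN	TRP	CB	CH2
ASSIGN	TRP	CG	CARO
ASSIGN	TRP	CD1	CTHI
ASSIGN	TRP	CD2	CTHI
ASSIGN	TRP	NE1	NARO
ASSIGN	TRP	CE2	CTHI
ASSIGN	TRP	CE3	CARO
ASSIGN	TRP	CZ2	CARO
ASSIGN	TRP	CZ3	CARO
ASSIGN	TRP	CH2	CARO
ASSIGN	TYR	N	NBB
ASSIGN	TYR	CA	CABB
ASSIGN	TYR	C	CBB
ASSIGN	TYR	O	OBB
ASSIGN	TYR	CB	CH2
ASSIGN	TYR	CG	CARO
ASSIGN	TYR	CD1	CARO
ASSIGN	TYR	CD2	CARO
ASSIGN	TYR	CE1	CARO
ASSIGN	TYR	CE2	CARO
ASSIGN	TYR	CZ	CFUN
ASSIGN	TYR	OH	OHYD
ASSIGN	VAL	N	NBB
ASSIGN	VAL	CA	CABB
ASSIGN	VAL	C	CBB
ASSIGN	VAL	O	OBB
ASSIGN	VAL	CB	CH2
ASSIGN	VAL	CG1	CH3
ASSIGN	VAL	CG2	CH3
ASSIGN	*	OXT	OCRB
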