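# Curated snapshot of common post-translational modification monoisotopic mass shifts.
# Columns: name, source_db, mono_delta (Da), kind, targets (one-letter residues, or "any").
name	source_db	mono_delta	kind	targets
Oxidation	unimod	15.994915	PTM	any
Dioxidation	unimod	31.989829	PTM	MWYFCH
Trioxidation	unimod	47.984744	PTM	C
Acetyl	unimod	42.010565	PTM	K
Phospho	unimod	79.966331	PTM	STY
Deamidated	unimod	0.984016	PTM	NQ
Amidated	unimod	-0.984016	PTM	any
Methyl	unimod	14.015650	PTM	KRHDE
Dimethyl	unimod	28.031300	PTM	KR
Trimethyl	unimod	42.046950	PTM	KR
Dehydrated	unimod	-18.010565	PTM	STDY
Dehydro	unimod	-1.007825	PTM	C
Carbamidomethyl	unimod	57.021464	PTM	C
Carbamyl	unimod	43.005814	PTM	K
Formyl	unimod	27.994915	PTM	K
GG	unimod	114.042927	PTM	K
Succinyl	unimod	100.016044	PTM	K
Malonyl	unimod	86.000394	PTM	K
Crotonyl	unimod	68.026215	PTM	K
Propionyl	unimod	56.026215	PTM	K
Butyryl	unimod	70.041865	PTM	K
Glutaryl	unimod	114.031694	PTM	K
2-Hydroxyisobutyryl	unimod	86.036779	PTM	K
Lactyl	unimod	72.021129	PTM	K
Nitro	unimod	44.985078	PTM	WY
Nitrosyl	unimod	28.990164	PTM	C
Cysteinyl	unimod	119.004099	PTM	C
Glutathione	unimod	305.068156	PTM	C
Methylthio	resid	45.987721	PTM	C
Sulfo	unimod	79.956815	PTM	STY
Hex	unimod	162.052824	PTM	STNK
HexNAc	unimod	203.079373	PTM	STN
dHex	unimod	146.057909	PTM	ST
NeuAc	unimod	291.095417	PTM	STN
Pentose	unimod	132.042259	PTM	ST
Myristoyl	unimod	210.198366	PTM	KGC
Palmitoyl	unimod	238.229666	PTM	KCST
Farnesyl	unimod	204.187801	PTM	C
GeranylGeranyl	unimod	272.250401	PTM	C
ADP-Ribose	unimod	541.061110	PTM	any
Phosphoadenosine	unimod	329.052520	PTM	any
Biotin	unimod	226.077598	PTM	K
Lipoyl	unimod	188.032956	PTM	K
Gln->pyro-Glu	unimod	-17.026549	PTM	Q
Glu->pyro-Glu	unimod	-18.010565	PTM	E
Pyridoxal-phosphate	expasy	229.014009	PTM	K
Retinal	expasy	266.203451	PTM	K
Hypusine	resid	87.068414	PTM	K
Carboxy	unimod	43.989829	PTM	KDEW
Carboxymethyl	unimod	58.005479	PTM	C
Hydroxymethyl	unimod	30.010565	PTM	N
Ethanolamine	unimod	43.042199	PTM	DE
Homocysteine-thiolactone	abrf	-48.003371	PTM	M
Persulfide	unimod	31.972071	PTM	C
Ammonia-loss	unimod	-17.026549	PTM	NSTC
Water-loss	unimod	-18.010565	PTM	DE
Cation-Na	unimod	21.981943	PTM	DE
Cation-K	unimod	37.955882	PTM	DE
Iron	unimod	52.911464	PTM	DE
Zinc	unimod	61.913495	PTM	C
Cyano	abrf	24.995249	PTM	C
Delta-H2C2	unimod	26.015650	PTM	K
Hydroxyproline	resid	15.994915	PTM	P
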