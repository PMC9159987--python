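sample_id	taxon	matches_type	hybrid_formula	knox3	ibr3	cp_haplotype	ploidy	mode	maternal_knox3	maternal_ibr3	region	elevation
Chao2135	P. arisanensis	Y	-	F7F7F7	Y21Y87*	cxx	3	apo	F7	Y87	Taiwan	h
Yang191030002	P. arisanensis	Y	-	F7F23	Y21Y87	cxx	-	apo	F7	Y87	Taiwan	h
Chao2482	P. arisanensis	-	-	F4F5	Y21V22	cx	2	apo	F4 or F5	Y21	Taiwan	l
Chao2296	P. arisanensis	-	-	A5D4G1	S19T20*	cf'	3	apo	-	-	Taiwan	l
Hsu s.n.20130116	P. arisanensis	-	P. latipinna x P. arisanensis	D7F4F5	Y21V22W23	ca	3	apo	D7	W23	Taiwan	both
Chao2483	P. arisanensis	-	-	D5F3	W23Y24	ca	2	apo	D5	W23	China, Taiwan, Vietnam	l
Chao2867	P. arisanensis	-	-	D7F3G1	W5S14Y24	ca	3	apo	D7	W5	China	l
Chao2858	P. arisanensis	-	-	D7F3G1	S14V22W23	ca	3	apo	D7	W23	China	l
Hsu s.n.20130315	P. austrotaiwanensis	-	-	D3D5	W69W23	ct	2	apo	D3	W69	Taiwan	l
Kao 03037	P. biaurita	Y	-	-	S25S25	ci	-	-	G1	S25	Costa Rica	l
Chao2734	P. biaurita	-	-	G1G1	S14S14	ci	2	apo	G1	S14	Cambodia, Thailand, China	l
Chao2419	P. biaurita	-	-	G1G4	S19S19	ci	2	apo	G1	S19	Malaysia	l
Chao2752	P. biaurita	-	-	G1G3	S19S19	ci	-	apo	G1	S19	China, Thailand	l
Chao1317	P. biaurita	-	P. biaurita x P. arisanensis	F7G1	S14S19Y21	ci	-	apo	G1	S14 or S19	China	h
Chao2484	P. biaurita	-	P. biaurita x P. arisanensis	F7G1*	S14Y21S25	ci	3	apo	G1	S14 or S25	Taiwan	both
Chao2471	P. biaurita	-	P. biaurita x P. arisanensis	F7G1*	Y21S70*	ci	3	apo	G1	S70	Taiwan	both
Chao2478	P. biaurita	-	P. arisanensis x P. biaurita	F16G1	S14Y87	cxx	2	apo	F16	Y87	Taiwan	both
Yang191029002	P. biaurita	-	P. arisanensis x P. biaurita	F16G1	S14Y87	-	-	apo	G1	S14	Taiwan	h
Chao2869	P. biaurita	-	P. latipinna x P. biaurita	D7G1	S25W23	ca'	2	apo	D7	W23	China	l
Chao1942	P. boninensis	Y	-	A7A7	T1T1	cb	2	sex	A7	T1	Japan	l
Chao1818	P. boninensis	-	P. boninensis x unknown	A1A7D5	W2T1*	cb	3	apo	A7	T1	Japan	l
Chao1819	P. boninensis	-	P. boninensis x unknown	A1A7D5	W2T1T7	cb	3	apo	A7	T1	Japan	l
Lu32448	P. confusa	Y	-	-	-	cc	-	apo	-	-	Sri Lanka	l
CRFJ FN 402	P. aff. confusa	-	-	F1F1	Y73Y73	-	-	apo	F1	Y73	Nepal	l
CRFJ 34934	P. aff. confusa	-	-	F1F2	-	-	-	apo	F1	Y73	India	l
Chao2082	P. fauriei	Y	P. minor x P. latipinna	A1A6D7	W5T1*	cf	3	apo	A1 or A6	T1	Japan, Taiwan	l
Yang191005005	P. fauriei	Y	P. minor x P. latipinna	A1D7*	W5T1*	cf	3	apo	A1	T1	Taiwan	l
Chao2668	P. fauriei	Y	P. minor x P. latipinna	A6D7	W5T1	cf	2	apo	A6	T1	Taiwan	l
Chao2667	P. fauriei	Y	P. minor x P. latipinna	A6D7*	W5T1*	cf	3	apo	A6	T1	China, Japan, Taiwan	l
Chao2051	P. fauriei	-	-	A3A5D7	W5T1*	cf	3	apo	A3 or A5	T1	Japan	l
Chao2805	P. fauriei	-	-	A11D32*	W5T1*	cf	3	apo	A?	T1	Taiwan	l
Chao2790	P. fauriei	-	P. minor x P. latipinna	A1A13D7	W5T1	cf	-	apo	A1	T1	Taiwan	l
Chao2155	P. cf. fauriei	-	P. oshimensis var. oshimensis x P. latipinna	A4D7	W5T1	cf	2	apo	A4	T1	Taiwan	l
Chao2156	P. cf. fauriei	-	P. oshimensis var. oshimensis x P. latipinna	A4D7*	T1T4W23	cf	3	apo	A4	T1	Taiwan	l
Wade3659-1	P. cf. fauriei	-	-	A5A12D8	W5T1T4	cf	3	apo	A5 or A12	T1 or T4	Japan	l
Chao2028	P. cf. fauriei	-	-	C1D1	V12X79	cs	2	apo	C1	X79	Japan	l
Chao2035	P. cf. fauriei	-	P. wulaiensis x P. latipinna	D4D7	W28W23	cy	2	apo	D4	W28	Japan, Taiwan	l
Chao2553	P. cf. fauriei	-	P. wulaiensis x P. latipinna	D4D7	W29W23	cy	2	apo	D4	W29	Taiwan	l
Lu25409	P. cf. fauriei	-	P. wulaiensis x P. latipinna	D4D7	W5W28	cy	-	apo	D4	W28	China	l
Lu22877	P. kawabatae	Y	-	C3E2	V41V86	ce	-	apo	E2	V86	Taiwan	l
Chao2170	P. kawabatae	-	-	B4D2H4	S14W52X82	cs	-	apo	B4	X82	China	l
Lu28259	P. kawabatae	-	-	B4D5H1	W23X82Y11	cs	3	apo	B4	X82	Taiwan	l
Lu28430B	P. kawabatae	-	-	B4H3	X82Y11	cs	2	apo	B4	X82	Taiwan	l
Knapp 4145	P. kawabatae	-	-	C3D7E2	W23V41V86	ca	-	apo	D7	W23	Taiwan	l
Chao2022	P. kawabatae	-	-	C3D1	V12W75	cl	2	apo	D1	W75	Japan	l
Chao1852	P. kiuschiuensis	Y	-	C3H1	V12Y11	ck	2	apo	H1	Y11	China, Japan	l
Ebihara et al. 3240	P. kiuschiuensis	-	-	C3D4H1	W5W78Y11	cy	3	apo	D4	W78	Japan	l
Lu24743	P. kiuschiuensis	-	-	C3D4H1	W78V12Y11	cy	3	apo	D4	W78	China, Japan	l
Chao2182	P. kiuschiuensis	-	-	D4D7H1	V12Y11W29	ck	-	apo	H1=H6	Y11	China	l
Chao2092	P. latipinna	Y	-	D7D7	W5W5	ca	2	apo	D7	W5	China, Taiwan	l
ZXC001673	P. latipinna	-	-	D7D7	W2W2	ca	-	apo	D7	W2	Taiwan	l
Chao2555	P. laurisilvicola	Y	-	A4A5D7	W30T1T4	cf	3	apo	A4	T1	Japan, Taiwan	l
Chao2528	P. laurisilvicola	-	-	A4A6D7	W5T1T4	cf	3	apo	A4 or A6	T1	Taiwan	l
Chao2891	P. laurisilvicola	-	-	A4A6D7	W30T1T4	cf	3	apo	A4 or A6	T1	Taiwan	l
Chao2078	P. minor	Y	-	A1A1	T1T1	cf	2	sex	A1	T1	Taiwan	l
Chao2647	P. minor	Y	-	A1A13	T1T1	cf	2	sex	A1	T1	Taiwan	l
Chao2500	P. minor	Y	-	A1A6	T31T31	cf'	2	sex	A1 or A6	T31	Taiwan	l
Hsu 8425	P. minor	Y	-	A6A6	T1T1	cf	2	sex	A6	T1	Taiwan	l
Chao2653	P. minor	Y	-	A6A6	T27T27	cf'	2	sex	A6	T27	Taiwan	l
Chao1842	P. natiensis	Y	unknown x P. latipinna	C3D7	V12W23	cn	2	apo	C3	V12	Japan	l
Chao2017	P. natiensis	-	-	C3D4D7	V12W28W23	cy	3	apo	D4	W28	China, Japan	l
Chao1881	P. oshimensis var. oshimensis	-	P. oshimensis var. oshimensis x unknown	A4D1	T1W75	cf	2	apo	A4	T1	Japan	l
Kuo3445	P. oshimensis var. oshimensis	Y	-	A4A4	T1T1	cf	2	sex	A4	T1	Japan	l
Zhang et al.20100430109	P. oshimensis var. paraemeiensis	Y	-	-	-	cs	-	apo	-	-	China	l
Hsu 8437	P. pseudowulaiensis	-	-	D1D5	W5W52	cw	-	apo	D5	W5	Taiwan	l
Ko33986	P. pseudowulaiensis	-	-	D2D5	W52W23	cw	2	apo	D5	W23	China	l
Wade2315	P. pseudowulaiensis	-	P. wulaiensis x unknown	D4D5	W5W28	cy	2	apo	D4	W28	China, Taiwan	l
Chao1925	P. satsumana	Y	-	B1C3	V12X82	cs	2	apo	B1	X82	Japan	l
Chao2526	P. setulosocostulata	Y	-	D4H4H10	W52Y11W89	ch	3	apo	H4	Y11	Taiwan	l
Chao1363	P. setulosocostulata	-	-	B2H3H5	X82Y11	ch	-	apo	H3	Y11	China	l
Hsu9088	P. wulaiensis	Y	-	D2D4	W52W75	cd	2	apo	D2	W52	Taiwan	l
Ebihara et al. 3234	P. wulaiensis	-	-	D4D4	W78W78	cy	2	apo	D4	W75	Japan	l
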