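sample_id	stipe_color	venation	elevation_range
Chao2135	stramineous_or_green	triangular	high
Yang191030002	stramineous_or_green	triangular	high
Chao2482	stramineous_or_green	triangular	low
Chao2296	red_brown	areolate	low
Hsu s.n.20130116	stramineous_or_green	triangular	high
Chao2483	stramineous_or_green	triangular	low
Chao2867	stramineous_or_green	areolate	low
Chao2858	stramineous_or_green	areolate	low
Hsu s.n.20130315	stramineous_or_green	free	low
Chao2734	stramineous_or_green	areolate	low
Chao2419	stramineous_or_green	areolate	low
Chao2752	stramineous_or_green	areolate	low
Chao1317	stramineous_or_green	areolate	high
Chao2484	stramineous_or_green	areolate	high
Chao2471	stramineous_or_green	areolate	high
Chao2478	stramineous_or_green	areolate	high
Yang191029002	stramineous_or_green	areolate	high
Chao2869	stramineous_or_green	areolate	low
Chao1942	stramineous_or_green	free	low
Chao1818	stramineous_or_green	free	low
Chao1819	stramineous_or_green	free	low
CRFJ FN 402	stramineous_or_green	triangular	low
CRFJ 34934	stramineous_or_green	triangular	low
Chao2082	stramineous_or_green	free	low
Yang191005005	stramineous_or_green	free	low
Chao2668	stramineous_or_green	free	low
Chao2667	stramineous_or_green	free	low
Chao2051	stramineous_or_green	free	low
Chao2805	stramineous_or_green	free	low
Chao2790	stramineous_or_green	free	low
Chao2155	stramineous_or_green	free	low
Chao2156	stramineous_or_green	free	low
Wade3659-1	stramineous_or_green	free	low
Chao2028	stramineous_or_green	free	low
Chao2035	red_brown	free	low
Chao2553	red_brown	free	low
Lu25409	red_brown	free	low
Lu22877	stramineous_or_green	free	low
Chao2170	stramineous_or_green	free	low
Lu28259	stramineous_or_green	free	low
Lu28430B	stramineous_or_green	free	low
Knapp 4145	stramineous_or_green	free	low
Chao2022	stramineous_or_green	free	low
Chao1852	stramineous_or_green	free	low
Ebihara et al. 3240	red_brown	free	low
Lu24743	red_brown	free	low
Chao2182	red_brown	free	low
Chao2092	stramineous_or_green	free	low
ZXC001673	stramineous_or_green	free	low
Chao2555	stramineous_or_green	free	low
Chao2528	stramineous_or_green	free	low
Chao2891	stramineous_or_green	free	low
Chao2078	stramineous_or_green	free	low
Chao2647	stramineous_or_green	free	low
Chao2500	stramineous_or_green	free	low
Hsu 8425	stramineous_or_green	free	low
Chao2653	stramineous_or_green	free	low
Chao1842	stramineous_or_green	free	low
Chao2017	red_brown	free	low
Chao1881	stramineous_or_green	free	low
Kuo3445	stramineous_or_green	free	low
Hsu 8437	stramineous_or_green	free	low
Ko33986	stramineous_or_green	free	low
Wade2315	red_brown	free	low
Chao1925	stramineous_or_green	free	low
Chao2526	red_brown	free	low
Chao1363	stramineous_or_green	free	low
Hsu9088	red_brown	free	low
Ebihara et al. 3234	red_brown	free	low
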