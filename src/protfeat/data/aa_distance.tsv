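# Amino-acid distance matrix used by the quasi-sequence-order descriptors.
# Constructed from three z-scored physicochemical properties — side-chain
# hydrophobicity (FAUJ830101), hydrophilicity (HOPT810101) and side-chain
# volume (GRAR740103) — as the Euclidean distance in that 3-space, scaled
# so the maximum pairwise distance equals 1.  Symmetric, zero diagonal.
aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.000000	0.258894	0.417283	0.456782	0.567384	0.147102	0.293487	0.472611	0.581034	0.461827	0.382352	0.215534	0.091817	0.270926	0.598031	0.103514	0.135257	0.309033	0.777568	0.518686
C	0.258894	0.000000	0.589022	0.585045	0.379475	0.383919	0.325398	0.268079	0.683073	0.265324	0.233581	0.417940	0.209106	0.375377	0.695358	0.338987	0.248304	0.151678	0.584283	0.400864
D	0.417283	0.589022	0.000000	0.132329	0.809090	0.403979	0.431858	0.726075	0.294439	0.713828	0.614363	0.282137	0.420837	0.329284	0.317169	0.318410	0.392259	0.599541	1.000000	0.722003
E	0.456782	0.585045	0.132329	0.000000	0.746882	0.482925	0.383166	0.674392	0.174241	0.661876	0.563248	0.305340	0.454036	0.291140	0.196492	0.371385	0.392225	0.569079	0.924489	0.653741
F	0.567384	0.379475	0.809090	0.746882	0.000000	0.713784	0.403168	0.117400	0.759427	0.118586	0.200148	0.623751	0.549386	0.508726	0.760607	0.629976	0.476953	0.260260	0.211107	0.157563
G	0.147102	0.383919	0.403979	0.482925	0.713784	0.000000	0.420833	0.616824	0.628597	0.606816	0.528367	0.263647	0.188802	0.370637	0.648363	0.133705	0.267668	0.454540	0.924110	0.664152
H	0.293487	0.325398	0.431858	0.383166	0.403168	0.420833	0.000000	0.345007	0.420956	0.328167	0.224443	0.236098	0.309526	0.107830	0.428854	0.299710	0.159175	0.233412	0.592993	0.297891
I	0.472611	0.268079	0.726075	0.674392	0.117400	0.616824	0.345007	0.000000	0.710187	0.018705	0.120812	0.549954	0.444108	0.443197	0.714420	0.536823	0.391028	0.165342	0.320552	0.199413
K	0.581034	0.683073	0.294439	0.174241	0.759427	0.628597	0.420956	0.710187	0.000000	0.696557	0.601282	0.404577	0.585635	0.350017	0.022737	0.506811	0.487966	0.631124	0.910933	0.648191
L	0.461827	0.265324	0.713828	0.661876	0.118586	0.606816	0.328167	0.018705	0.696557	0.000000	0.104675	0.534794	0.435918	0.427362	0.700773	0.525027	0.377460	0.153718	0.325964	0.185033
M	0.382352	0.233581	0.614363	0.563248	0.200148	0.528367	0.224443	0.120812	0.601282	0.104675	0.000000	0.433601	0.363005	0.322711	0.606614	0.435064	0.282810	0.096314	0.406897	0.178602
N	0.215534	0.417940	0.282137	0.305340	0.623751	0.263647	0.236098	0.549954	0.404577	0.534794	0.433601	0.000000	0.269212	0.148230	0.421212	0.150535	0.173163	0.400762	0.821850	0.525828
P	0.091817	0.209106	0.420837	0.454036	0.549386	0.188802	0.309526	0.444108	0.585635	0.435918	0.363005	0.269212	0.000000	0.294565	0.602728	0.145312	0.159208	0.290926	0.760285	0.520101
Q	0.270926	0.375377	0.329284	0.291140	0.508726	0.370637	0.107830	0.443197	0.350017	0.427362	0.322711	0.148230	0.294565	0.000000	0.361866	0.240306	0.152495	0.318611	0.699000	0.404517
R	0.598031	0.695358	0.317169	0.196492	0.760607	0.648363	0.428854	0.714420	0.022737	0.700773	0.606614	0.421212	0.602728	0.361866	0.000000	0.525554	0.502042	0.639506	0.908069	0.648057
S	0.103514	0.338987	0.318410	0.371385	0.629976	0.133705	0.299710	0.536823	0.506811	0.525027	0.435064	0.150535	0.145312	0.240306	0.525554	0.000000	0.158037	0.377351	0.838877	0.565938
T	0.135257	0.248304	0.392259	0.392225	0.476953	0.267668	0.159175	0.391028	0.487966	0.377460	0.282810	0.173163	0.159208	0.152495	0.502042	0.158037	0.000000	0.234532	0.683896	0.407998
V	0.309033	0.151678	0.599541	0.569079	0.260260	0.454540	0.233412	0.165342	0.631124	0.153718	0.096314	0.400762	0.290926	0.318611	0.639506	0.377351	0.234532	0.000000	0.471240	0.251346
W	0.777568	0.584283	1.000000	0.924489	0.211107	0.924110	0.592993	0.320552	0.910933	0.325964	0.406897	0.821850	0.760285	0.699000	0.908069	0.838877	0.683896	0.471240	0.000000	0.305939
Y	0.518686	0.400864	0.722003	0.653741	0.157563	0.664152	0.297891	0.199413	0.648191	0.185033	0.178602	0.525828	0.520101	0.404517	0.648057	0.565938	0.407998	0.251346	0.305939	0.000000
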