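# K1/K10 subdomain boundaries (1-based, inclusive).
# Best reconstruction from published residue landmarks (1A start K1:181,
# 1B C-terminus K1:328/K10:296, V1 K1:61-153/K10:31-137, H2 K1:487-497/
# K10:453-460, V2 K1:497-607/K10:461-558) combined with canonical IF rod
# subdomain lengths (1A 35, L1 11, 1B 101, L12 16, 2A 19, L2 8).
# Edit freely: every analysis accepts a user-supplied table.
chain	subdomain	start	end
K1	E1	1	60
K1	V1	61	153
K1	H1	154	180
K1	1A	181	215
K1	L1	216	226
K1	1B	227	327
K1	L12	328	343
K1	2A	344	362
K1	L2	363	370
K1	2B	371	486
K1	H2	487	496
K1	V2	497	607
K1	E2	608	644
K10	E1	1	30
K10	V1	31	137
K10	H1	138	148
K10	1A	149	183
K10	L1	184	194
K10	1B	195	295
K10	L12	296	311
K10	2A	312	330
K10	L2	331	338
K10	2B	339	452
K10	H2	453	460
K10	V2	461	558
K10	E2	559	584
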