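chrom	start_bp	end_bp	source
1	47761741	51822307	literature
2	129125957	139525961	literature
2	182309767	189427029	literature
3	47483506	49987563	literature
3	83368159	86868160	literature
3	161899518	163699518	literature
5	98636396	101136397	literature
5	129636408	132636409	literature
5	136136412	139136412	literature
6	23691793	38924246	literature
6	139637170	142137170	literature
8	6455071	13598120	literature
8	110918595	113918595	literature
11	88127184	91127184	literature
12	110577812	113099475	literature
14	47061047	47961047	literature
17	42394456	46567318	literature
20	33948533	36438183	literature
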