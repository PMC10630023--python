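node	degree	betweenness	role
APOA1	31	0.36595308	hub
TF	23	0.40234675	hub
GC	19	0.16563324	hub
HP	17	0.13375361	hub
FGG	17	0.11910425	hub
FGB	15	0.06095966	hub
FGA	14	0.05532558	hub
APOB	14	0.02554443	hub
CDC20	4	0.59090909	bottleneck
FBXO5	4	0.45454545	bottleneck
NUP107	5	0.43181818	bottleneck
TF	23	0.40234675	bottleneck
APOA1	31	0.36595308	bottleneck
SEH1L	5	0.18939394	bottleneck
GC	19	0.16563324	bottleneck
TUBB3	2	0.13796193	bottleneck
HP	17	0.13375361	bottleneck
KRT1	11	0.1318414	bottleneck
ARHGEF7	2	0.11959686	bottleneck
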