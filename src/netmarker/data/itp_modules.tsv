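cluster	n_nodes	n_edges	score	input_proteins	members
1	11	56	11	APOA1;TF;GC;FGG;HP;FGB;RBP4	GC;APOB;RBP4;APOA1;TF;APOA2;FGG;APOC3;FGA;FGB;HP
2	4	6	4	KRT1	KRT5;EVPL;KRT1;DSP
3	4	6	4	SEH1L	MIOS;NPRL2;SEH1L;WDR24
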