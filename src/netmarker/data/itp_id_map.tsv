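# UniProt entry-name stem -> HGNC gene symbol
K2C1	KRT1
VTDB	GC
FIBB	FGB
FIBG	FGG
ZF69B	ZFP69B
HPT	HP
APOA1	APOA1
FBX5	FBXO5
RET4	RBP4
DYRK4	DYRK4
KLH25	KLHL25
SCRIB	SCRIB
K1C27	KRT27
SEH1	SEH1L
TRFE	TF
K1C10	KRT10
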