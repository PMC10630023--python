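spot_id,mascot_id,gene,score,direction,fold_change,p_value
1,K2C1_HUMAN,KRT1,73,down,3.7,0.049
2,VTDB_HUMAN,GC,70,down,1.7,0.049
3,FIBB_HUMAN,FGB,115,down,2,0.049
4,FIBB_HUMAN,FGB,120,down,3.7,0.049
5,FIBG_HUMAN,FGG,144,down,1.7,0.049
6,ZF69B_HUMAN,ZFP69B,38,down,1.9,0.049
7,HPT_HUMAN,HP,127,down,1.7,0.049
8,HPT_HUMAN,HP,123,down,2.6,0.049
9,APOA1_HUMAN,APOA1,174,down,3.1,0.049
10,FBX5_HUMAN,FBXO5,43,down,2.1,0.049
11,RET4_HUMAN,RBP4,72,down,5.4,0.049
12,DYRK4_HUMAN,DYRK4,35,down,3.8,0.049
13,KLH25_HUMAN,KLHL25,42,down,4.1,0.049
14,SCRIB_HUMAN,SCRIB,48,down,2.2,0.049
15,K1C27_HUMAN,KRT27,42,down,2.4,0.049
16,SEH1_HUMAN,SEH1L,34,down,2.6,0.049
17,TRFE_HUMAN,TF,183,down,1.6,0.049
18,TRFE_HUMAN,TF,141,down,1.7,0.049
19,K1C10_HUMAN,KRT10,118,up,2,0.049
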