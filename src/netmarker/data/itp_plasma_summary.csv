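protein,group,mean,sd,n
APOA1,respondent,18.03571,10.6335,8
APOA1,nonrespondent,6.302083,3.672867,8
APOA1,control,16.18519,3.047306,10
VTDB,respondent,4.064286,2.529134,8
VTDB,nonrespondent,1.235417,0.962695,8
VTDB,control,4.383333,2.440059,10
TRFE,respondent,7.752747,2.944662,8
TRFE,nonrespondent,3.835165,1.10778,8
TRFE,control,10.24786,2.665811,10
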