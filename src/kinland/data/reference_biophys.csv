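# Measured SPR dissociation constants (nM, ± SD of duplicates) and DSF
# thermal shifts (°C) for cyclin-free CDK1/CDK2. Experimental inputs only.
inhibitor,kinase,spr_kd_nM,spr_sd_nM,delta_tm_C
Dinaciclib,CDK1,1810,150,0.51
Dinaciclib,CDK2,78,16,2.6
AZD5438,CDK1,1560,220,-2.6
AZD5438,CDK2,43,8.1,8.9
Alvocidib,CDK1,1080,200,0.9
Alvocidib,CDK2,650,230,7.3
CGP74514A,CDK1,13500,1000,-3.3
CGP74514A,CDK2,312,52,5.2
SU9516,CDK1,5840,720,-1.5
SU9516,CDK2,56,26,11.7
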