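# Measured apo melting temperatures of monomeric CDK1/CDK2 (°C, DSC).
kinase,tm_C,sd_C
CDK1,48.9,0.04
CDK2,51.52,0.05
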