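# Measured ITC dissociation constants (nM, mean ± SD of two replicates)
# for five ATP-competitive inhibitors against cyclin-bound and cyclin-free
# CDK1/CDK2. Entries flagged bounded did not reach saturation; only a
# lower bound on Kd (20 uM) is known. These are experimental inputs: they
# seed generator truths and table-formatting fixtures, they are not
# computed by this package.
inhibitor,state,kd_nM,sd_nM,bounded
Dinaciclib,CDK1-cyclin B,32,2,False
Dinaciclib,CDK2-cyclin A,2,1,False
Dinaciclib,CDK1,955,246,False
Dinaciclib,CDK2,41,14,False
AZD5438,CDK1-cyclin B,70,13,False
AZD5438,CDK2-cyclin A,4,1,False
AZD5438,CDK1,4400,3200,False
AZD5438,CDK2,26,3,False
Alvocidib,CDK1-cyclin B,28,6,False
Alvocidib,CDK2-cyclin A,23,3,False
Alvocidib,CDK1,1600,300,False
Alvocidib,CDK2,217,1,False
CGP74514A,CDK1-cyclin B,950,50,False
CGP74514A,CDK2-cyclin A,224,14,False
CGP74514A,CDK1,20000,,True
CGP74514A,CDK2,715,15,False
SU9516,CDK1-cyclin B,234,20,False
SU9516,CDK2-cyclin A,25,5,False
SU9516,CDK1,20000,,True
SU9516,CDK2,98,1,False
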