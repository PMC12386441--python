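trinucleotide,gc_content,at_content,purine_fraction,keto_fraction,amino_fraction,stacking_energy,melting_enthalpy,yr_step_fraction,at_run,cpg_step,base_diversity
AAA,0.000000,1.000000,1.000000,0.000000,1.000000,0.816949,0.766667,0.000000,1.000000,0.000000,0.000000
AAC,0.333333,0.666667,0.666667,0.000000,1.000000,0.667797,0.683333,0.000000,0.666667,0.000000,0.500000
AAG,0.333333,0.666667,1.000000,0.333333,0.666667,0.722034,0.783333,0.000000,0.666667,0.000000,0.500000
AAT,0.000000,1.000000,0.666667,0.333333,0.666667,0.857627,0.883333,0.000000,1.000000,0.000000,0.500000
ACA,0.333333,0.666667,0.666667,0.000000,1.000000,0.515254,0.583333,1.000000,0.333333,0.000000,0.500000
ACC,0.666667,0.333333,0.333333,0.000000,1.000000,0.383051,0.666667,0.000000,0.333333,0.000000,0.500000
ACG,0.666667,0.333333,0.666667,0.333333,0.666667,0.271186,0.233333,1.000000,0.333333,1.000000,1.000000
ACT,0.333333,0.666667,0.333333,0.333333,0.666667,0.572881,0.700000,0.000000,0.333333,0.000000,1.000000
AGA,0.333333,0.666667,1.000000,0.333333,0.666667,0.620339,0.733333,0.000000,0.333333,0.000000,0.500000
AGC,0.666667,0.333333,0.666667,0.333333,0.666667,0.301695,0.466667,0.000000,0.333333,0.000000,1.000000
AGG,0.666667,0.333333,1.000000,0.666667,0.333333,0.437288,0.766667,0.000000,0.333333,0.000000,0.500000
AGT,0.333333,0.666667,0.666667,0.666667,0.333333,0.572881,0.700000,0.000000,0.333333,0.000000,1.000000
ATA,0.000000,1.000000,0.666667,0.333333,0.666667,1.000000,1.000000,1.000000,1.000000,0.000000,0.500000
ATC,0.333333,0.666667,0.333333,0.333333,0.666667,0.755932,0.833333,0.000000,0.666667,0.000000,1.000000
ATG,0.333333,0.666667,0.666667,0.666667,0.333333,0.705085,0.783333,1.000000,0.666667,0.000000,1.000000
ATT,0.000000,1.000000,0.333333,0.666667,0.333333,0.857627,0.883333,0.000000,1.000000,0.000000,0.500000
CAA,0.333333,0.666667,0.666667,0.000000,1.000000,0.664407,0.666667,1.000000,0.666667,0.000000,0.500000
CAC,0.666667,0.333333,0.333333,0.000000,1.000000,0.515254,0.583333,1.000000,0.333333,0.000000,0.500000
CAG,0.666667,0.333333,0.666667,0.333333,0.666667,0.569492,0.683333,1.000000,0.333333,0.000000,1.000000
CAT,0.333333,0.666667,0.333333,0.333333,0.666667,0.705085,0.783333,1.000000,0.666667,0.000000,1.000000
CCA,0.666667,0.333333,0.333333,0.000000,1.000000,0.379661,0.650000,1.000000,0.333333,0.000000,0.500000
CCC,1.000000,0.000000,0.000000,0.000000,1.000000,0.247458,0.733333,0.000000,0.000000,0.000000,0.000000
CCG,1.000000,0.000000,0.333333,0.333333,0.666667,0.135593,0.300000,1.000000,0.000000,1.000000,0.500000
CCT,0.666667,0.333333,0.000000,0.333333,0.666667,0.437288,0.766667,0.000000,0.333333,0.000000,0.500000
CGA,0.666667,0.333333,0.666667,0.333333,0.666667,0.318644,0.266667,1.000000,0.333333,1.000000,1.000000
CGC,1.000000,0.000000,0.333333,0.333333,0.666667,0.000000,0.000000,1.000000,0.000000,1.000000,0.500000
CGG,1.000000,0.000000,0.666667,0.666667,0.333333,0.135593,0.300000,1.000000,0.000000,1.000000,0.500000
CGT,0.666667,0.333333,0.333333,0.666667,0.333333,0.271186,0.233333,1.000000,0.333333,1.000000,1.000000
CTA,0.333333,0.666667,0.333333,0.333333,0.666667,0.864407,0.900000,1.000000,0.666667,0.000000,1.000000
CTC,0.666667,0.333333,0.000000,0.333333,0.666667,0.620339,0.733333,0.000000,0.333333,0.000000,0.500000
CTG,0.666667,0.333333,0.333333,0.666667,0.333333,0.569492,0.683333,1.000000,0.333333,0.000000,1.000000
CTT,0.333333,0.666667,0.000000,0.666667,0.333333,0.722034,0.783333,0.000000,0.666667,0.000000,0.500000
GAA,0.333333,0.666667,1.000000,0.333333,0.666667,0.715254,0.716667,0.000000,0.666667,0.000000,0.500000
GAC,0.666667,0.333333,0.666667,0.333333,0.666667,0.566102,0.633333,0.000000,0.333333,0.000000,1.000000
GAG,0.666667,0.333333,1.000000,0.666667,0.333333,0.620339,0.733333,0.000000,0.333333,0.000000,0.500000
GAT,0.333333,0.666667,0.666667,0.666667,0.333333,0.755932,0.833333,0.000000,0.666667,0.000000,1.000000
GCA,0.666667,0.333333,0.666667,0.333333,0.666667,0.244068,0.350000,1.000000,0.333333,0.000000,1.000000
GCC,1.000000,0.000000,0.333333,0.333333,0.666667,0.111864,0.433333,0.000000,0.000000,0.000000,0.500000
GCG,1.000000,0.000000,0.666667,0.666667,0.333333,0.000000,0.000000,1.000000,0.000000,1.000000,0.500000
GCT,0.666667,0.333333,0.333333,0.666667,0.333333,0.301695,0.466667,0.000000,0.333333,0.000000,1.000000
GGA,0.666667,0.333333,1.000000,0.666667,0.333333,0.430508,0.700000,0.000000,0.333333,0.000000,0.500000
GGC,1.000000,0.000000,0.666667,0.666667,0.333333,0.111864,0.433333,0.000000,0.000000,0.000000,0.500000
GGG,1.000000,0.000000,1.000000,1.000000,0.000000,0.247458,0.733333,0.000000,0.000000,0.000000,0.000000
GGT,0.666667,0.333333,0.666667,1.000000,0.000000,0.383051,0.666667,0.000000,0.333333,0.000000,0.500000
GTA,0.333333,0.666667,0.666667,0.666667,0.333333,0.810169,0.800000,1.000000,0.666667,0.000000,1.000000
GTC,0.666667,0.333333,0.333333,0.666667,0.333333,0.566102,0.633333,0.000000,0.333333,0.000000,1.000000
GTG,0.666667,0.333333,0.666667,1.000000,0.000000,0.515254,0.583333,1.000000,0.333333,0.000000,0.500000
GTT,0.333333,0.666667,0.333333,1.000000,0.000000,0.667797,0.683333,0.000000,0.666667,0.000000,0.500000
TAA,0.000000,1.000000,0.666667,0.333333,0.666667,0.959322,0.883333,1.000000,1.000000,0.000000,0.500000
TAC,0.333333,0.666667,0.333333,0.333333,0.666667,0.810169,0.800000,1.000000,0.666667,0.000000,1.000000
TAG,0.333333,0.666667,0.666667,0.666667,0.333333,0.864407,0.900000,1.000000,0.666667,0.000000,1.000000
TAT,0.000000,1.000000,0.333333,0.666667,0.333333,1.000000,1.000000,1.000000,1.000000,0.000000,0.500000
TCA,0.333333,0.666667,0.333333,0.333333,0.666667,0.562712,0.616667,1.000000,0.333333,0.000000,1.000000
TCC,0.666667,0.333333,0.000000,0.333333,0.666667,0.430508,0.700000,0.000000,0.333333,0.000000,0.500000
TCG,0.666667,0.333333,0.333333,0.666667,0.333333,0.318644,0.266667,1.000000,0.333333,1.000000,1.000000
TCT,0.333333,0.666667,0.000000,0.666667,0.333333,0.620339,0.733333,0.000000,0.333333,0.000000,0.500000
TGA,0.333333,0.666667,0.666667,0.666667,0.333333,0.562712,0.616667,1.000000,0.333333,0.000000,1.000000
TGC,0.666667,0.333333,0.333333,0.666667,0.333333,0.244068,0.350000,1.000000,0.333333,0.000000,1.000000
TGG,0.666667,0.333333,0.666667,1.000000,0.000000,0.379661,0.650000,1.000000,0.333333,0.000000,0.500000
TGT,0.333333,0.666667,0.333333,1.000000,0.000000,0.515254,0.583333,1.000000,0.333333,0.000000,0.500000
TTA,0.000000,1.000000,0.333333,0.666667,0.333333,0.959322,0.883333,1.000000,1.000000,0.000000,0.500000
TTC,0.333333,0.666667,0.000000,0.666667,0.333333,0.715254,0.716667,0.000000,0.666667,0.000000,0.500000
TTG,0.333333,0.666667,0.333333,1.000000,0.000000,0.664407,0.666667,1.000000,0.666667,0.000000,0.500000
TTT,0.000000,1.000000,0.000000,1.000000,0.000000,0.816949,0.766667,0.000000,1.000000,0.000000,0.000000
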