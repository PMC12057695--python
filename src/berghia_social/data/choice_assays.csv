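assay,deprivation_days,acclimation,n_tested,n_social,n_omitted
ST,7,ASW,40,23,2
ST,7,ATW,15,6,1
ST,3,ATW,18,9,1
FC,7,ASW,24,6,1
FC,7,ATW,28,13,0
ST+FC,7,ASW,22,9,2
ST+FC,3,ATW,16,10,0
BA,7,ASW,28,11,2
MA,7,ATW,30,8,1
MA,3,ATW,17,7,1
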