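strain,dose_nM,polysaccharide_ugC_cm2,protein_ugBSA_cm2,eps_total_printed_ug_cm2
pao1,0,3.61,2.75,6.37
pao1,100,2.61,2.03,4.64
pao1,200,2.18,0.75,2.93
pao1,300,1.42,0.46,1.87
multi,0,4.90,3.44,8.34
multi,100,4.62,1.83,6.46
multi,200,4.05,0.85,4.90
multi,300,3.81,0.65,4.47
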