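strain,dose_nM,od_mean,od_sd,n
pao1,0,0.357,0.017,3
pao1,100,,,
pao1,200,,,
pao1,300,0.490,0.016,3
multi,0,0.292,0.050,3
multi,100,0.381,0.017,3
multi,200,0.416,0.028,3
multi,300,0.490,0.017,3
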