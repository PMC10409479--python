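strain,dose_nM,total_biomass_um3_um2,total_biomass_sd,sbr_um2_um3,sbr_sd,mean_thickness_um,mean_thickness_sd,roughness,roughness_sd
pao1,0,12.897,3.661,5.476,0.803,38.989,1.877,0.005,0.005
pao1,100,5.435,4.319,8.701,3.134,8.474,6.020,0.374,0.357
pao1,200,0.109,0.010,18.174,0.108,1.170,0.063,1.967,0.026
pao1,300,0.044,0.021,19.300,0.397,1.003,0.045,1.993,0.007
multi,0,26.071,2.980,4.237,0.283,43.914,0.679,0.002,0.004
multi,100,17.933,0.961,5.507,0.489,27.977,2.390,0.034,0.048
multi,200,7.619,1.876,6.397,1.163,12.077,1.073,0.051,0.037
multi,300,0.441,0.500,16.373,2.929,11.433,5.535,0.066,0.032
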