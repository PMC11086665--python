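# Average nonradiologist 80% detection thresholds, lung reference kernel
# (f_peak 4.64 lp/cm, sigma 1.83 lp/cm). d_fpeak / d_sigma in lp/cm;
# directions changing one parameter only carry 0 for the other.
direction,d_fpeak,d_sigma
1,0.40,0.0
2,-0.40,0.0
3,0.0,0.78
4,0.0,-0.37
5,0.18,0.26
6,-0.15,-0.21
7,0.75,-1.10
8,-1.23,1.73
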