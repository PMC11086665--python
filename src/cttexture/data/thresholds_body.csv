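# Average nonradiologist 80% detection thresholds, body reference kernel
# (f_peak 1.89 lp/cm, sigma 1.28 lp/cm). d_fpeak / d_sigma in lp/cm;
# directions changing one parameter only carry 0 for the other.
direction,d_fpeak,d_sigma
1,0.18,0.0
2,-0.21,0.0
3,0.0,0.16
4,0.0,-0.15
5,0.06,0.08
6,-0.07,-0.09
7,0.20,-0.26
8,-0.30,0.30
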