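sphere_diameter_mm,metric,reconstruction,mad
37,rc_mean,vendor_specific,0.01
28,rc_mean,vendor_specific,0.10
22,rc_mean,vendor_specific,0.20
17,rc_mean,vendor_specific,0.11
13,rc_mean,vendor_specific,0.09
37,rc_mean,vendor_neutral,0.05
28,rc_mean,vendor_neutral,0.02
22,rc_mean,vendor_neutral,0.04
17,rc_mean,vendor_neutral,0.04
13,rc_mean,vendor_neutral,0.04
37,rc_max,vendor_specific,0.03
28,rc_max,vendor_specific,0.16
22,rc_max,vendor_specific,0.28
17,rc_max,vendor_specific,0.18
13,rc_max,vendor_specific,0.13
37,rc_max,vendor_neutral,0.05
28,rc_max,vendor_neutral,0.04
22,rc_max,vendor_neutral,0.06
17,rc_max,vendor_neutral,0.11
13,rc_max,vendor_neutral,0.04
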