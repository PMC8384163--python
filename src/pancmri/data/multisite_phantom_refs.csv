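measure,reference
volume,89.0
t1_vial_1,500
t1_vial_2,1000
t1_vial_3,1250
t1_vial_4,1500
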