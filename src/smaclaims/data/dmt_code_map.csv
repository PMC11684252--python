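code,flag
J2326,dmt_nusinersen
J3399,dmt_onasemnogene
E0465,mechanical_ventilation
E0466,mechanical_ventilation
B4150,nutritional_support
B9002,nutritional_support
E1399,dme
K0005,dme
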