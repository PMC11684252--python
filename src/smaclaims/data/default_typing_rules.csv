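rule_id,priority,type,age_dx_lo,age_dx_hi,age_end_min,require_markers,exclude_markers
T1_SUPPORTED,10,1,0,2,,mechanical_ventilation;nutritional_support,
T1_INFANT,20,1,0,1,,,
T3_MILD_SURVIVOR,30,3,1,3,10,,mechanical_ventilation;nutritional_support
T2_TODDLER,40,2,1,3,,,
T3_CHILD,50,3,3,18,,,
T4_ADULT,60,4,18,inf,,,
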