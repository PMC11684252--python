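group,dx_prefix
scoliosis,M41
dyspnea_and_respiratory_anomalies,R06
muscle_weakness_generalized,M62.81
chronic_respiratory_failure,J96.1
feeding_difficulties,R63.3
neurodevelopmental_disorders,F80
neurodevelopmental_disorders,F82
neurodevelopmental_disorders,F84
elimination_disorders,F98.0
anxiety_disorders,F41
depressive_disorders,F32
depressive_disorders,F33
other_clinical_attention,Z71
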