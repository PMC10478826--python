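site	S_male	S_female	V_RM_male	V_RM_female	f_RM_male	f_RM_female	cellularity_pct
T_vertebrae	1.05E-04	1.35E-04	147.2	112.5	0.63	0.62	70
L_vertebrae	1.05E-04	1.08E-04	146.9	141.0	0.63	0.61	70
TL_vertebrae	5.25E-05	6.00E-05	294.0	253.5	0.63	0.62	70
hip_bones	3.85E-05	5.26E-05	299.7	225.5	0.43	0.46	48
skeletal_average	1.07E-05	1.40E-05	1170	904	0.52	0.47	NA
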