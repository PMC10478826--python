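patient_id	bone_metastases	vert_specific	vert_nonspecific	vert_total	hip_specific	hip_nonspecific	hip_total	blood_based	excluded_from_averages
1	No	0.068	0.026	0.093	0.066	0.019	0.085	0.015	No
2	No	0.025	0.019	0.044	0.016	0.014	0.030	0.011	No
3	Yes	0.016	0.018	0.033	0.028	0.013	0.042	0.012	No
4	No	0.022	0.014	0.036	0.014	0.011	0.025	0.010	No
5	Yes	0.496	0.028	0.524	0.251	0.022	0.273	0.019	Yes
6	No	0.018	0.016	0.034	0.022	0.012	0.034	0.011	No
7	No	0.020	0.023	0.042	0.012	0.017	0.028	0.017	No
8	No	0.029	0.021	0.050	0.039	0.015	0.054	0.012	No
9	No	0.038	0.024	0.062	0.028	0.017	0.045	0.013	No
10	No	0.047	0.023	0.070	0.024	0.017	0.040	0.013	No
11	Yes	0.065	0.041	0.106	0.049	0.030	0.079	0.023	No
12	Yes	0.052	0.025	0.077	0.040	0.018	0.058	0.014	No
13	No	0.052	0.041	0.093	0.030	0.030	0.059	0.023	No
14	Yes	0.056	0.037	0.093	0.069	0.027	0.096	0.021	No
15	Yes	0.114	0.042	0.157	0.084	0.032	0.116	0.029	No
16	Yes	0.026	0.013	0.039	0.020	0.010	0.030	0.009	No
17	No	0.043	0.043	0.086	0.052	0.033	0.085	0.029	No
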