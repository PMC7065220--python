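cultivar,rubisco_content,rubisco_content_se,initial_activity,initial_activity_se,total_activity,total_activity_se,activation_state,activation_state_se,specific_activity,specific_activity_se,total_rca,total_rca_se,rca_alpha,rca_alpha_se,rca_beta,rca_beta_se
Mbundumali,1.28,0.10,24.66,3.15,29.53,2.74,83.0,3.5,1.39,0.06,1.03,0.03,0.41,0.02,0.59,0.02
TME3,1.85,0.06,39.78,0.73,42.73,0.55,93.2,2.4,1.39,0.03,1.02,0.05,0.40,0.02,0.60,0.02
TME419,1.68,0.07,35.78,1.26,40.24,2.03,89.2,2.9,1.43,0.03,1.02,0.04,0.40,0.01,0.60,0.01
TME693,1.72,0.10,35.94,3.21,42.43,3.46,84.7,3.6,1.47,0.04,1.06,0.03,0.41,0.01,0.59,0.01
TME7,1.79,0.11,33.16,3.66,37.11,3.38,88.9,1.9,1.33,0.02,0.99,0.05,0.40,0.01,0.60,0.01
TMS01/1412,1.59,0.08,30.60,1.93,38.22,1.10,80.1,4.6,1.45,0.03,0.98,0.03,0.39,0.02,0.61,0.02
TMS30001,1.79,0.08,34.07,3.17,45.21,3.14,79.4,2.3,1.51,0.07,0.98,0.05,0.40,0.02,0.60,0.02
TMS30572,1.41,0.11,28.12,3.09,34.83,2.78,80.2,3.2,1.48,0.02,0.99,0.04,0.39,0.01,0.61,0.01
TMS96/1632,1.88,0.13,38.50,2.29,43.28,1.38,88.8,2.4,1.46,0.05,0.97,0.02,0.42,0.02,0.58,0.02
TMS97/2205,1.20,0.12,16.44,2.39,23.17,1.75,70.5,6.6,1.16,0.03,0.96,0.08,0.37,0.01,0.63,0.01
TMS98/0002,1.64,0.13,33.40,1.85,39.36,2.12,85.0,2.8,1.45,0.06,0.98,0.05,0.36,0.01,0.64,0.01
TMS98/0505,1.46,0.03,30.92,2.25,36.40,0.81,84.7,4.2,1.50,0.01,1.02,0.03,0.42,0.02,0.58,0.02
TMS98/0581,1.42,0.08,29.36,2.10,35.34,1.86,82.9,2.7,1.50,0.04,1.03,0.02,0.38,0.01,0.62,0.01
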