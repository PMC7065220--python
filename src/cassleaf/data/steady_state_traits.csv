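cultivar,asat,asat_se,vcmax,vcmax_se,vcmax_cc,vcmax_cc_se,jmax,jmax_se,vtpu,vtpu_se,gs,gs_se,iwue,iwue_se,operating_ci,operating_ci_se
Mbundumali,20.32,1.05,100.12,3.96,124.81,12.47,169.41,6.01,11.03,0.43,0.28,0.02,81.63,5.84,244.10,9.45
TME3,21.49,1.78,101.83,10.75,156.73,8.51,165.39,14.52,10.85,0.89,0.34,0.02,71.66,7.15,257.43,11.08
TME419,22.17,1.36,118.18,6.90,128.28,5.98,183.86,14.78,11.65,0.81,0.27,0.02,83.07,4.48,241.21,7.69
TME693,23.22,1.27,110.29,7.42,133.19,13.71,171.30,11.08,11.43,0.70,0.33,0.02,75.41,4.01,252.96,6.77
TME7,24.61,1.60,104.82,2.72,140.44,8.79,163.45,7.47,10.90,0.36,0.34,0.03,74.22,4.88,254.91,7.70
TMS01/1412,24.81,1.22,113.48,3.83,135.62,6.05,175.88,11.59,11.46,0.68,0.32,0.01,73.35,4.85,255.77,7.73
TMS30001,22.95,1.27,117.16,6.87,136.24,7.21,169.67,5.73,11.13,0.26,0.28,0.02,86.57,4.52,235.19,7.33
TMS30572,20.81,0.95,95.24,4.83,120.63,9.86,154.50,10.56,9.97,0.50,0.32,0.04,72.92,6.13,258.15,9.35
TMS96/1632,24.21,1.23,102.65,6.75,141.65,9.45,163.24,14.20,10.83,0.70,0.33,0.01,71.49,3.38,258.63,5.12
TMS97/2205,22.12,0.37,100.33,2.70,122.47,10.80,157.68,7.50,10.77,0.51,0.25,0.02,93.48,6.91,226.83,10.84
TMS98/0002,21.92,1.26,96.28,2.23,119.68,8.70,149.36,10.15,10.50,0.69,0.29,0.03,78.96,8.99,249.02,13.49
TMS98/0505,21.49,0.62,97.06,11.21,132.68,9.55,161.15,13.25,10.45,0.70,0.30,0.01,78.70,1.32,250.41,2.23
TMS98/0581,23.11,1.12,99.33,4.36,138.67,7.60,148.69,4.63,9.88,0.24,0.31,0.02,73.47,5.31,257.31,8.53
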