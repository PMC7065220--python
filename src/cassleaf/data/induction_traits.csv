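cultivar,t50a,t50a_se,t90a,t90a_se,ccf,ccf_se,gst0,gst0_se,t50gs,t50gs_se
Mbundumali,4.2,0.3,13.8,0.6,272,20.7,0.032,0.006,8.08,0.52
TME3,6.1,0.4,15.5,1.2,187,22.7,0.016,0.003,7.70,0.58
TME419,4.6,0.7,14.0,1.5,291,24.3,0.027,0.006,7.38,1.20
TME693,10.6,1.4,21.2,1.1,122,27.2,0.005,0.004,9.48,2.11
TME7,6.4,0.5,17.0,1.6,201,35.4,0.019,0.003,10.58,1.43
TMS01/1412,3.5,0.5,17.1,1.5,179,31.6,0.025,0.006,5.75,0.96
TMS30001,4.1,0.5,17.1,2.2,280,46.2,0.028,0.006,6.21,0.55
TMS30572,5.1,0.7,13.3,1.6,262,40.5,0.020,0.005,7.67,0.55
TMS96/1632,4.5,0.8,17.8,1.3,276,45.8,0.045,0.008,10.33,1.32
TMS97/2205,3.1,1.0,11.3,0.5,333,46.1,0.054,0.013,7.40,0.92
TMS98/0002,4.0,0.7,16.4,2.2,279,41.2,0.032,0.013,5.73,0.67
TMS98/0505,3.1,0.2,11.6,0.7,349,16.1,0.047,0.003,7.18,1.78
TMS98/0581,4.2,0.6,17.6,1.6,226,33.9,0.034,0.015,7.36,0.69
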