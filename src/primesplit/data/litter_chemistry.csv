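litter_code,N,N_se,C,C_se,L,L_se,Ce,Ce_se,Ss,Ss_se,phM,phM_se,phW,phW_se,Ct,Ct_se,d13C,d13C_se
Ah,17.74,0.15,441.59,0.15,160.37,2.13,138.33,0.91,48.15,0.42,61.66,0.61,65.39,0.24,18.93,0.11,-28.59,0.02
Cm,36.84,0.14,445.22,0.71,132.94,1.82,137.06,1.77,42.27,0.52,36.76,0.31,25.39,0.23,8.94,0.24,-27.93,0.03
Ps,6.75,0.17,410.33,0.17,146.68,1.32,177.15,0.92,71.12,0.37,57.89,1.20,72.14,0.57,88.98,2.19,-28.05,0.03
AhCm,28.48,0.36,446.28,0.53,152.35,0.53,121.35,0.68,41.31,0.64,37.78,0.47,38.88,0.23,7.21,0.33,-28.13,0.09
AhPs,12.77,0.18,426.07,0.29,155.18,0.94,167.32,0.36,52.14,0.17,55.92,1.12,59.77,0.74,34.97,0.22,-28.32,0.04
CmPs,23.75,0.22,429.53,0.69,145.51,1.88,169.59,1.27,50.34,0.73,30.76,0.29,42.37,0.76,26.03,0.05,-27.87,0.07
AhCmPs,20.72,0.07,431.04,0.31,148.03,0.78,172.08,0.58,42.53,0.76,40.08,0.96,43.77,0.58,15.40,0.73,-27.89,0.07
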