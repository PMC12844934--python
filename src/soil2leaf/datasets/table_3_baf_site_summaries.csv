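site_id,element,mean,sem,n
S1,Cd,1.31,0.06,4
S1,Cu,0.53,0.04,4
S1,Ni,0.09,0.01,4
S1,Pb,0.01,0.01,4
S1,Zn,0.51,0.03,4
S1,Fe,17.74,0.91,4
S1,Mn,9.89,0.60,4
S2,Cd,1.54,0.17,4
S2,Cu,0.56,0.06,4
S2,Ni,0.09,0.01,4
S2,Pb,0.01,0.01,4
S2,Zn,0.50,0.01,4
S2,Fe,31.79,2.08,4
S2,Mn,8.17,0.01,4
S3,Cd,4.32,0.17,4
S3,Cu,0.63,0.07,4
S3,Ni,0.09,0.01,4
S3,Pb,0.02,0.01,4
S3,Zn,0.50,0.01,4
S3,Fe,26.81,1.66,4
S3,Mn,9.88,0.83,4
S4,Cd,3.94,0.54,4
S4,Cu,0.58,0.04,4
S4,Ni,0.10,0.01,4
S4,Pb,0.01,0.01,4
S4,Zn,0.48,0.03,4
S4,Fe,50.78,3.19,4
S4,Mn,9.86,0.66,4
S5,Cd,6.71,0.54,4
S5,Cu,0.49,0.03,4
S5,Ni,0.09,0.01,4
S5,Pb,0.01,0.01,4
S5,Zn,0.47,0.02,4
S5,Fe,52.88,0.73,4
S5,Mn,10.02,0.23,4
S6,Cd,1.78,0.19,4
S6,Cu,0.49,0.02,4
S6,Ni,0.10,0.01,4
S6,Pb,0.02,0.01,4
S6,Zn,0.51,0.03,4
S6,Fe,43.09,3.10,4
S6,Mn,10.11,0.22,4
S7,Cd,0.87,0.15,4
S7,Cu,0.43,0.03,4
S7,Ni,0.08,0.01,4
S7,Pb,0.01,0.01,4
S7,Zn,0.50,0.01,4
S7,Fe,32.45,1.92,4
S7,Mn,7.88,0.01,4
S8,Cd,2.20,0.27,4
S8,Cu,0.51,0.05,4
S8,Ni,0.10,0.01,4
S8,Pb,0.01,0.01,4
S8,Zn,0.52,0.02,4
S8,Fe,31.88,2.82,4
S8,Mn,10.20,0.52,4
S9,Cd,5.20,0.77,4
S9,Cu,0.48,0.05,4
S9,Ni,0.09,0.01,4
S9,Pb,0.02,0.01,4
S9,Zn,0.51,0.04,4
S9,Fe,41.85,2.49,4
S9,Mn,10.16,0.91,4
S10,Cd,5.47,0.45,4
S10,Cu,0.52,0.05,4
S10,Ni,0.10,0.01,4
S10,Pb,0.02,0.01,4
S10,Zn,0.53,0.03,4
S10,Fe,22.17,1.40,4
S10,Mn,10.46,0.17,4
S11,Cd,2.67,0.26,4
S11,Cu,0.46,0.03,4
S11,Ni,0.10,0.01,4
S11,Pb,0.02,0.01,4
S11,Zn,0.49,0.02,4
S11,Fe,24.24,1.43,4
S11,Mn,9.46,0.40,4
S12,Cd,2.33,0.30,4
S12,Cu,0.50,0.02,4
S12,Ni,0.09,0.01,4
S12,Pb,0.02,0.01,4
S12,Zn,0.55,0.01,4
S12,Fe,27.62,1.90,4
S12,Mn,9.55,0.18,4
S13,Cd,8.42,1.41,4
S13,Cu,0.44,0.05,4
S13,Ni,0.09,0.01,4
S13,Pb,0.02,0.01,4
S13,Zn,0.53,0.02,4
S13,Fe,22.68,0.40,4
S13,Mn,9.16,0.55,4
S14,Cd,1.84,0.05,4
S14,Cu,0.45,0.05,4
S14,Ni,0.09,0.01,4
S14,Pb,0.02,0.01,4
S14,Zn,0.51,0.03,4
S14,Fe,46.36,3.62,4
S14,Mn,12.04,1.12,4
S15,Cd,4.02,0.51,4
S15,Cu,0.49,0.11,4
S15,Ni,0.09,0.01,4
S15,Pb,0.02,0.01,4
S15,Zn,0.50,0.01,4
S15,Fe,51.07,3.26,4
S15,Mn,11.39,1.19,4
S16,Cd,4.18,0.48,4
S16,Cu,0.49,0.04,4
S16,Ni,0.09,0.01,4
S16,Pb,0.02,0.01,4
S16,Zn,0.55,0.01,4
S16,Fe,49.13,3.94,4
S16,Mn,12.83,0.01,4
S17,Cd,5.13,0.41,4
S17,Cu,0.59,0.04,4
S17,Ni,0.09,0.01,4
S17,Pb,0.04,0.01,4
S17,Zn,0.47,0.01,4
S17,Fe,51.38,2.93,4
S17,Mn,37.29,4.58,4
S18,Cd,4.13,0.08,4
S18,Cu,0.56,0.05,4
S18,Ni,0.08,0.01,4
S18,Pb,0.03,0.01,4
S18,Zn,0.50,0.01,4
S18,Fe,25.21,0.91,4
S18,Mn,9.43,0.98,4
S19,Cd,1.75,0.12,4
S19,Cu,0.53,0.02,4
S19,Ni,0.06,0.01,4
S19,Pb,0.01,0.01,4
S19,Zn,0.47,0.01,4
S19,Fe,53.11,2.92,4
S19,Mn,14.46,0.01,4
S20,Cd,2.51,0.28,4
S20,Cu,0.53,0.03,4
S20,Ni,0.07,0.01,4
S20,Pb,0.01,0.01,4
S20,Zn,0.42,0.01,4
S20,Fe,22.87,0.91,4
S20,Mn,11.93,1.94,4
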