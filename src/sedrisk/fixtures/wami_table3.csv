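station,As_mean,As_sd,Cd_mean,Cd_sd,Cr_mean,Cr_sd,Cu_mean,Cu_sd,Pb_mean,Pb_sd,Zn_mean,Zn_sd
1,1.23,0.06,0.45,0.03,34.64,2.70,37.96,2.34,19.24,1.36,68.72,3.79
2,1.12,0.08,0.36,0.04,50.32,3.43,36.6,3.29,19.80,1.36,77.2,5.82
3,0.57,0.04,0.80,0.05,65.61,4.64,44.73,2.75,19.69,2.08,95.24,2.16
4,1.87,0.10,0.36,0.04,34.45,2.44,36.67,2.42,18.93,0.83,62.07,4.00
5,0.90,0.07,0.32,0.06,37.93,5.36,26.07,1.01,18.50,2.11,62.57,9.29
6,3.14,0.25,0.53,0.05,31.74,3.03,32.21,2.59,18.17,1.29,65.17,4.17
7,1.70,0.13,0.32,0.02,54.65,8.12,37.68,3.72,18.52,1.70,78.42,7.21
8,0.40,0.05,0.45,0.03,60.88,4.30,39.3,3.42,16.68,1.41,85.8,7.28
9,1.10,0.09,0.35,0.04,53.38,4.91,39.02,3.71,18.52,1.57,92.15,7.83
10,0.70,0.03,0.49,0.02,39.78,3.38,55.14,5.00,21.78,0.98,112.38,1.96
11,0.52,0.01,0.44,0.03,53.78,4.56,16.28,1.72,19.18,1.44,94.75,2.48
12,2.40,0.07,0.36,0.05,58.74,5.20,31.71,2.95,22.33,2.21,92.11,9.12
13,2.33,0.27,0.41,0.02,58.74,6.15,31.71,2.16,21.42,1.58,92.11,6.50
14,1.43,0.15,0.38,0.03,42.70,4.22,20.82,1.18,16.77,1.30,88.25,6.87
15,5.92,0.12,0.42,0.04,28.98,2.05,68.14,3.67,19.32,1.91,60.74,6.02
16,0.77,0.05,0.21,0.02,45.60,3.56,42.28,2.33,19.67,1.67,86.05,7.30
17,1.76,0.07,0.24,0.01,54.10,5.35,31.12,1.92,17.30,1.22,83.16,5.89
18,1.87,0.15,0.16,0.01,56.5,4.80,36.32,2.63,18.32,1.68,94.35,8.68
19,1.13,0.08,0.20,0.01,35.71,2.52,33.6,3.18,19.71,1.95,73.5,7.28
20,1.94,0.12,0.19,0.01,41.38,3.79,38.2,2.61,18.02,1.28,81.05,5.74
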