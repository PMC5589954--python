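patient,Sigma_S,Sigma_D,Sigma_C_si,sigma_C_si,Sigma_C_lr,sigma_C_lr,Sigma_C_ap,sigma_C_ap,Sigma_P_si,sigma_P_si,Sigma_P_lr,sigma_P_lr,Sigma_P_ap,sigma_P_ap,Sigma_T_si,Sigma_T_lr,Sigma_T_ap
1,0.54,0.75,0.4,0.6,0.3,1.0,0.1,1.0,0.0,0.0,0.0,0.1,0.0,0.1,0.18,0.33,0.25
2,0.54,0.75,0.1,0.8,0.4,1.3,0.2,1.1,0.0,0.2,0.0,0.2,0.0,0.1,0.18,0.33,0.25
3,0.54,0.75,0.3,1.5,0.4,1.6,0.4,1.6,0.0,0.1,0.0,0.1,0.0,0.1,0.18,0.33,0.25
4,0.54,0.75,0.3,1.0,0.3,1.3,0.3,1.3,0.0,0.1,0.0,0.2,0.0,0.2,0.18,0.33,0.25
5,0.54,1.25,0.3,0.9,0.1,0.5,0.1,0.5,0.0,0.2,0.0,0.2,0.0,0.0,0.18,0.33,0.25
6,0.54,1.25,0.2,1.0,0.1,0.6,0.3,1.6,0.0,0.1,0.0,0.1,0.0,0.1,0.18,0.33,0.25
7,0.54,0.75,0.2,0.9,0.1,0.6,0.1,0.7,0.0,0.1,0.0,0.1,0.0,0.0,0.18,0.33,0.25
8,0.54,0.75,1.4,2.2,0.2,0.4,0.1,0.5,0.0,0.3,0.0,0.3,0.0,0.1,0.18,0.33,0.25
9,0.54,0.75,0.2,1.0,0.1,0.3,0.1,0.3,0.0,0.2,0.0,0.1,0.0,0.0,0.18,0.33,0.25
10,0.54,0.75,0.7,1.6,0.2,1.8,0.1,1.3,0.0,0.2,0.0,0.1,0.0,0.0,0.18,0.33,0.25
11,0.54,0.75,0.3,0.5,0.1,0.4,0.1,0.4,0.0,0.0,0.0,0.0,0.0,0.0,0.18,0.33,0.25
12,0.54,0.75,0.1,1.8,0.0,1.1,1.0,2.6,0.0,0.3,0.0,0.3,0.0,0.4,0.18,0.33,0.25
13,0.54,0.75,0.2,0.8,0.4,0.6,0.0,0.3,0.0,0.2,0.0,0.2,0.0,0.0,0.18,0.33,0.25
14,0.54,0.75,0.8,2.1,0.3,0.8,0.9,2.2,0.0,0.4,0.0,0.4,0.0,0.2,0.18,0.33,0.25
15,0.54,0.75,0.3,1.0,0.1,0.5,0.1,0.4,0.0,0.0,0.0,0.0,0.0,0.0,0.18,0.33,0.25
16,0.54,0.75,0.7,1.4,0.2,0.6,0.3,0.8,0.0,0.1,0.0,0.2,0.0,0.0,0.18,0.33,0.25
17,0.54,0.75,0.6,1.3,0.2,1.0,0.4,1.9,0.0,0.3,0.0,0.2,0.0,0.1,0.18,0.33,0.25
18,0.54,0.75,0.2,0.7,0.1,0.6,0.1,0.9,0.0,0.0,0.0,0.0,0.0,0.1,0.18,0.33,0.25
19,0.54,0.75,0.6,1.4,0.2,0.8,0.3,0.9,0.0,0.3,0.0,0.3,0.0,0.1,0.18,0.33,0.25
20,0.54,0.75,0.2,0.5,0.1,0.5,0.1,0.4,0.0,0.0,0.0,0.0,0.0,0.0,0.18,0.33,0.25
21,0.54,0.75,0.2,0.8,0.2,0.9,0.2,1.0,0.0,0.0,0.0,0.0,0.0,0.1,0.18,0.33,0.25
22,0.54,0.75,0.3,1.0,0.1,0.8,0.3,0.9,0.0,0.1,0.0,0.0,0.0,0.1,0.18,0.33,0.25
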