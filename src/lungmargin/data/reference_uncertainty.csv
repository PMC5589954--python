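patient,U_S,U_D,U_C_si,U_C_lr,U_C_ap,U_P_si,U_P_lr,U_P_ap,U_T_si,U_T_lr,U_T_ap
1,1.46,1.5,0.9,0.9,0.5,0.0,0.0,0.0,0.49,0.86,0.64
2,1.46,1.5,0.6,1.0,0.5,0.0,0.0,0.0,0.49,0.86,0.64
3,1.46,1.5,0.7,1.1,1.1,0.0,0.0,0.0,0.49,0.86,0.64
4,1.46,1.5,0.8,0.9,0.9,0.0,0.0,0.0,0.49,0.86,0.64
5,1.46,2.5,0.8,0.4,0.4,0.0,0.0,0.0,0.49,0.86,0.64
6,1.46,2.5,0.8,0.4,1.0,0.0,0.0,0.0,0.49,0.86,0.64
7,1.46,1.5,0.5,0.4,0.2,0.0,0.0,0.0,0.49,0.86,0.64
8,1.46,1.5,1.5,0.3,0.2,0.0,0.0,0.0,0.49,0.86,0.64
9,1.46,1.5,0.2,0.2,0.2,0.0,0.0,0.0,0.49,0.86,0.64
10,1.46,1.5,0.8,0.2,0.2,0.0,0.0,0.0,0.49,0.86,0.64
11,1.46,1.5,0.3,0.2,0.2,0.0,0.0,0.0,0.49,0.86,0.64
12,1.46,1.5,1.5,0.2,2.9,0.0,0.0,0.0,0.49,0.86,0.64
13,1.46,1.5,0.8,1.3,0.2,0.0,0.0,0.0,0.49,0.86,0.64
14,1.46,1.5,3.1,0.7,3.0,0.0,0.0,0.0,0.49,0.86,0.64
15,1.46,1.5,0.9,0.5,0.5,0.0,0.0,0.0,0.49,0.86,0.64
16,1.46,1.5,2.6,0.6,1.2,0.0,0.0,0.0,0.49,0.86,0.64
17,1.46,1.5,1.7,0.8,2.1,0.0,0.0,0.0,0.49,0.86,0.64
18,1.46,1.5,0.5,0.3,0.3,0.0,0.0,0.0,0.49,0.86,0.64
19,1.46,1.5,2.0,0.5,1.0,0.0,0.0,0.0,0.49,0.86,0.64
20,1.46,1.5,0.6,0.4,0.4,0.0,0.0,0.0,0.49,0.86,0.64
21,1.46,1.5,0.6,0.7,1.1,0.0,0.0,0.0,0.49,0.86,0.64
22,1.46,1.5,0.8,0.3,0.7,0.0,0.0,0.0,0.49,0.86,0.64
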