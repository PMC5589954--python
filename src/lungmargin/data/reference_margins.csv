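patient,M_si,M_lr,M_ap,U_si,U_lr,U_ap
1,2.6,2.7,2.5,2.4,2.5,2.3
2,2.5,2.8,2.6,2.3,2.5,2.3
3,2.7,2.9,2.8,2.3,2.6,2.5
4,2.6,2.7,2.7,2.3,2.5,2.4
5,3.6,3.6,3.5,3.1,3.1,3.0
6,3.6,3.6,3.8,3.1,3.1,3.2
7,2.5,2.5,2.5,2.3,2.3,2.2
8,4.6,2.6,2.5,2.7,2.3,2.2
9,2.5,2.5,2.5,2.2,2.3,2.2
10,3.2,2.8,2.6,2.3,2.3,2.2
11,2.5,2.5,2.5,2.2,2.3,2.2
12,2.6,2.6,3.9,2.7,2.3,3.7
13,2.5,2.7,2.4,2.3,2.7,2.2
14,3.4,2.7,3.6,3.8,2.4,3.8
15,2.6,2.5,2.5,2.4,2.4,2.3
16,3.1,2.6,2.6,3.4,2.4,2.5
17,3.0,2.6,2.9,2.8,2.5,3.1
18,2.5,2.5,2.5,2.3,2.3,2.3
19,3.0,2.6,2.6,3.0,2.4,2.5
20,2.5,2.5,2.5,2.3,2.3,2.3
21,2.5,2.6,2.6,2.3,2.4,2.5
22,2.6,2.6,2.6,2.3,2.3,2.3
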