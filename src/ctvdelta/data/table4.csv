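case,ctvl_d2,ctvl_d95,ctvl_d98,delta_d98
1,104.7,99.6,97.9,89.8
2,104.3,99.8,98.2,96.7
3,104.5,99.7,97.9,95.6
4,104.0,99.6,97.0,94.1
5,104.5,99.8,98.4,96.7
6,103.9,99.6,98.5,98.1
7,104.8,97.5,94.8,85.1
8,104.3,99.5,97.9,94.1
9,105.0,99.2,97.3,97.5
10,104.4,99.7,98.2,96.5
11,105.5,99.2,97.0,85.6
12,105.7,99.4,97.3,67.1
13,105.2,98.7,96.7,91.9
14,105.3,99.0,97.1,92.5
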