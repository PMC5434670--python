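id,age,age_of_onset,illness_duration_years,ia,resting_rsa_ln_ms2
1,22,19,3,0.36,5.08
2,13,12,1,0.30,3.86
3,19,17,2,0.51,2.80
4,39,18,21,0.71,3.23
5,44,17,27,0.41,2.15
6,31,15,16,0.25,2.39
7,15,15,0,0.53,1.79
8,17,16,1,0.35,4.03
9,32,17,15,0.30,3.67
10,16,15,1,0.33,5.93
12,23,15,8,0.36,6.14
13,22,14,8,0.66,2.65
14,23,16,7,0.69,5.10
15,17,14,3,0.37,3.48
16,21,20,1,0.67,3.61
17,21,21,0,0.36,3.82
18,27,24,3,0.55,2.03
19,48,24,24,0.73,1.55
20,24,19,5,0.34,5.06
21,15,14,1,0.59,2.76
22,16,14,2,0.84,3.07
23,17,16,1,0.37,4.19
24,16,15,1,0.57,4.90
25,15,14,1,0.35,6.25
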