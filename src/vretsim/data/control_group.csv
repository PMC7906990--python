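participant,state1_maintenance,state1_less_anxious,state1_more_anxious,state1_entrance_time,state1_recovery_duration,state2_maintenance,state2_less_anxious,state2_more_anxious,state2_entrance_time,state2_recovery_duration
1,12.04,19.58,28.38,5.54,11.20,24.54,4.41,31.05,2.33,3.57
2,25.25,19.25,15.50,4.06,5.52,22.12,19.56,18.32,9.28,7.40
3,27.18,24.53,8.29,1.31,3.51,22.53,32.23,5.25,15.0,3.39
4,34.19,17.28,8.53,6.40,4.42,12.94,33.50,13.56,21.15,4.40
5,32.26,13.50,14.24,2.32,10.0,12.93,2.54,44.53,1.18,8.13
6,37.02,13.52,9.46,9.31,5.39,15.88,37.11,7.01,3.02,6.55
7,34.56,20.42,5.02,5.18,3.16,30.04,14.44,15.52,4.35,12.19
8,23.33,34.20,2.47,9.25,3.27,13.08,19.56,27.36,11.16,8.06
9,39.53,15.27,5.20,4.50,9.46,8.72,41.19,10.09,38.28,5.42
10,20.33,13.57,26.10,1.10,12.51,15.55,44.45,0.0,33.34,14.36
11,22.29,26.16,11.55,3.51,7.29,35.08,21.53,3.39,3.54,1.55
12,13.51,22.46,24.03,7.19,9.11,5.77,4.23,50.0,5.35,19.54
13,15.29,27.53,17.18,6.30,4.17,9.11,16.59,34.30,3.37,11.44
14,10.03,30.46,19.51,2.07,9.57,17.57,18.25,24.18,11.53,0.57
15,18.44,20.09,21.47,10.51,7.40,4.61,7.29,48.10,2.09,17.21
16,45.37,11.42,3.20,5.29,1.18,10.50,49.50,0.0,8.54,3.05
17,44.23,10.59,5.18,3.53,8.50,32.15,21.56,6.29,7.12,5.33
18,41.11,18.50,1.39,1.10,0.54,5.95,54.05,0.0,5.55,3.50
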