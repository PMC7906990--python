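participant,state1_maintenance,state1_less_anxious,state1_more_anxious,state1_entrance_time,state1_recovery_duration,state2_maintenance,state2_less_anxious,state2_more_anxious,state2_entrance_time,state2_recovery_duration
1,44.77,14.01,1.22,4.14,5.09,32.13,24.37,3.50,17.26,5.34
2,53.63,5.19,1.18,2.58,11.56,55.59,3.33,1.08,1.16,1.51
3,43.10,13.55,3.35,7.02,13.02,39.05,20.51,0.44,13.19,7.38
4,38.54,14.20,7.26,8.34,6.28,50.32,7.42,2.26,5.52,3.11
5,33.46,24.10,1.45,10.08,7.25,27.41,29.07,3.52,15.54,10.06
6,35.34,19.46,5.19,9.06,7.25,34.41,20.40,5.19,7.24,14.26
7,40.15,13.50,6.35,8.04,12.16,40.58,12.12,7.30,3.56,15.51
8,33.10,8.42,18.48,4.35,8.34,35.19,7.51,17.3,3.20,13.16
9,39.12,18.34,2.54,5.46,10.58,54.30,3.16,2.54,1.24,3.08
10,42.14,15.37,2.49,4.22,9.06,37.32,20.25,2.43,12.42,5.18
11,45.28,14.26,0.46,7.46,6.36,38.10,21.34,0.56,19.50,11.25
12,53.15,3.50,3.05,1.41,5.02,48.52,5.28,6.20,2.31,9.09
13,56.35,3.45,0.19,0.54,2.56,46.42,11.31,2.27,4.24,4.23
14,52.20,6.51,1.29,3.20,1.51,47.51,12.29,0.20,3.55,7.18
15,51.15,5.33,3.52,2.19,8.03,48.47,7.37,4.16,6.37,8.50
16,49.52,8.12,2.36,4.48,3.41,30.55,24.25,5.20,16.50,13.24
17,47.57,7.18,5.25,3.20,5.57,33.58,17.29,9.13,9.50,18.39
18,43.40,12.33,4.27,1.57,3.94,27.42,29.57,3.01,5.44,6.51
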