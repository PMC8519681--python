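depth_mm,energy_mev,modeled,standard,deviation_pct
0,6,81.45,81.76,-0.38
5,6,96.70,96.35,0.36
10,6,99.95,99.71,0.25
15,6,97.00,95.77,1.29
20,6,76.57,72.44,5.70
25,6,33.84,35.63,-5.02
30,6,9.20,8.74,5.34
35,6,2.92,1.30,124.63
40,6,1.57,0.84,86.20
0,9,76.71,79.83,-3.90
5,9,85.11,85.66,-0.64
10,9,92.18,90.93,1.37
15,9,97.26,96.16,1.15
20,9,99.89,99.70,0.19
25,9,98.10,97.56,0.55
30,9,86.44,85.75,0.80
35,9,58.82,62.81,-6.36
40,9,29.71,35.45,-16.20
45,9,14.04,13.41,4.66
50,9,5.89,3.44,71.55
55,9,2.33,1.25,86.79
60,9,1.33,1.08,22.61
0,12,79.93,83.34,-4.09
5,12,88.65,88.33,0.36
10,12,93.74,91.84,2.07
15,12,97.08,95.01,2.18
20,12,99.17,97.63,1.58
25,12,100.00,99.56,0.44
30,12,99.07,99.53,-0.46
35,12,95.08,94.82,0.28
40,12,85.13,83.98,1.37
45,12,65.55,66.22,-1.01
50,12,40.43,44.03,-8.19
55,12,21.63,23.15,-6.56
60,12,11.25,9.22,22.02
65,12,5.71,3.50,62.96
0,15,86.37,89.98,-4.02
5,15,95.05,94.06,1.05
10,15,97.83,96.45,1.43
15,15,99.20,97.84,1.39
20,15,99.85,98.86,1.01
25,15,99.99,99.66,0.33
30,15,99.63,99.75,-0.12
35,15,98.69,99.24,-0.55
40,15,96.89,97.21,-0.33
45,15,93.64,93.30,0.36
50,15,87.77,86.37,1.62
55,15,77.30,75.88,1.88
60,15,60.60,62.10,-2.42
65,15,40.86,46.10,-11.37
70,15,25.12,30.31,-17.11
75,15,15.51,17.14,-9.53
80,15,10.09,8.70,15.93
85,15,6.20,4.84,28.09
90,15,5.08,3.76,35.11
95,15,3.87,3.54,9.11
100,15,3.05,3.47,-12.00
105,15,2.48,3.38,-26.67
110,15,2.07,3.31,-37.45
0,18,90.84,87.85,3.41
5,18,93.33,92.08,1.36
10,18,95.23,94.29,1.00
15,18,96.74,95.93,0.85
20,18,97.95,97.11,0.86
25,18,98.89,98.34,0.56
30,18,99.56,99.20,0.37
35,18,99.95,99.74,0.20
40,18,99.94,99.98,-0.04
45,18,99.37,99.16,0.21
50,18,97.89,96.86,1.06
55,18,94.76,92.34,2.62
60,18,88.57,84.79,4.46
65,18,76.99,73.93,4.14
70,18,58.70,60.03,-2.22
75,18,38.40,44.28,-13.29
80,18,24.30,29.22,-16.86
85,18,14.39,16.66,-13.62
90,18,9.39,8.74,7.38
95,18,6.49,5.10,27.19
100,18,4.71,4.02,17.23
105,18,3.56,3.76,-5.29
110,18,2.78,3.70,-24.85
115,18,2.22,3.61,-38.41
120,18,1.82,3.53,-48.47
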