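depth_mm,cone_cm,modeled,standard,deviation_pct
0,6,82.29,83.83,-1.84
0,10,79.93,83.34,-4.09
0,15,79.93,82.8,-3.47
0,20,79.93,83.24,-3.98
0,25,79.93,83.1,-3.81
5,6,89.59,89.04,0.62
5,10,88.49,88.27,0.25
5,15,88.49,88.12,0.42
5,20,88.49,88.29,0.23
5,25,88.49,88.04,0.51
10,6,94.26,92.65,1.74
10,10,93.68,91.81,2.04
10,15,93.68,91.8,2.05
10,20,93.68,91.75,2.10
10,25,93.68,91.65,2.21
15,6,97.35,95.69,1.73
15,10,97.05,95.01,2.15
15,15,97.05,94.9,2.27
15,20,97.05,94.8,2.37
15,25,97.05,94.63,2.56
20,6,99.3,98.33,0.99
20,10,99.17,97.63,1.58
20,15,99.17,97.76,1.44
20,20,99.17,97.57,1.64
20,25,99.17,97.55,1.66
25,6,100,99.88,0.12
25,10,100,99.56,0.44
25,15,100,99.71,0.29
25,20,100,99.64,0.36
25,25,100,99.61,0.39
30,6,98.92,98.93,-0.01
30,10,99.04,99.47,-0.43
30,15,99.04,99.11,-0.07
30,20,99.04,99.19,-0.15
30,25,99.04,99.19,-0.15
35,6,94.79,93.35,1.54
35,10,95.08,94.82,0.27
35,15,95.08,93.86,1.30
35,20,95.08,94.37,0.75
35,25,95.08,93.78,1.39
40,6,84.52,81.65,3.52
40,10,85.13,83.98,1.37
40,15,85.13,82,3.82
40,20,85.13,82.56,3.11
40,25,85.13,81.76,4.12
45,6,64.59,63.5,1.72
45,10,65.55,66.22,-1.01
45,15,65.55,63.91,2.57
45,20,65.55,64.22,2.07
45,25,65.55,62.98,4.08
50,6,39.93,41.84,-4.57
50,10,43.58,44.39,-1.82
50,15,40.58,41.83,-2.99
50,20,40.58,42.06,-3.52
50,25,40.58,40.81,-0.56
55,6,21.97,22.03,-0.27
55,10,21.9,23.63,-7.32
55,15,21.39,21.5,-0.51
55,20,21.9,21.97,-0.32
55,25,21.9,20.99,4.34
60,6,8.87,8.46,4.85
60,10,9.25,9.22,0.33
60,15,8.25,8.19,0.73
60,20,8.25,8.54,-3.40
60,25,8.25,8.09,1.98
65,6,3.49,3.32,2.71
65,10,3.67,3.64,0.82
65,15,3.77,3.32,7.53
65,20,3.28,3.42,-4.09
65,25,3.18,3.27,-2.75
70,6,2.31,2.16,2.31
70,10,2.53,2.31,5.19
70,15,2.25,2.23,5.38
70,20,2.25,2.22,1.35
70,25,2.15,2.14,0.47
75,6,2.13,2.04,4.41
75,10,2.15,2.19,-1.83
75,15,2.25,2.15,4.65
75,20,2.15,2.14,0.47
75,25,2.25,2.06,9.22
80,6,2.43,2.49,-2.41
80,10,2.18,2.14,1.87
80,15,2.08,2.13,-2.35
80,20,2.28,2.31,-1.30
80,25,2.35,2.47,-4.86
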