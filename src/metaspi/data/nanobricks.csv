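num,a_nm,b_nm,delta_x,t_x,delta_y,t_y
1,78,160,3.07,0.85,0.62,0.4
2,82,156,-2.81,0.83,0.32,0.74
3,86,152,-2.32,0.83,0.36,0.68
4,88,150,-2.11,0.88,0.44,0.53
5,92,160,-1.46,0.92,0.23,0.95
6,96,160,-1.10,1,0.38,0.94
7,104,40,1.48,0.96,0.69,0.98
8,104,158,-0.60,0.96,0.53,0.91
9,112,152,-0.24,0.99,0.49,0.91
10,116,40,1.86,0.95,0.72,0.98
11,126,144,0.18,0.98,0.50,0.92
12,130,40,2.33,0.97,0.76,0.98
13,140,40,2.73,0.9,0.79,0.98
14,144,136,0.62,0.96,0.50,0.92
15,152,40,-3.14,0.78,0.82,0.98
16,160,130,1.03,0.85,0.47,0.92
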