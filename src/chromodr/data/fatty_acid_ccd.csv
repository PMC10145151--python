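run_id,flow_rate,gradient_time,temperature,t_end_peak1,t_start_peak2,t_end_peak6,t_start_peak7,k_last
1,0.50,8.0,30.00,4.84,4.94,8.99,9.01,15.80
2,0.70,8.0,30.00,3.53,3.60,6.85,6.85,16.99
3,0.50,15.0,30.00,4.95,5.07,9.98,10.02,18.78
4,0.70,15.0,30.00,3.61,3.67,7.47,7.49,19.86
5,0.50,8.0,40.00,4.31,4.31,7.82,7.82,13.73
6,0.70,8.0,40.00,3.12,3.12,5.86,5.86,14.64
7,0.50,15.0,40.00,4.37,4.37,8.47,8.47,15.86
8,0.70,15.0,40.00,3.15,3.15,6.27,6.27,16.59
9,0.50,11.5,35.00,4.56,4.61,8.83,8.84,16.41
10,0.70,11.5,35.00,3.33,3.38,6.66,6.66,17.32
11,0.60,8.0,35.00,3.84,3.87,7.21,7.21,15.45
12,0.60,15.0,35.00,3.90,3.95,7.85,7.87,17.88
13,0.60,11.5,30.00,4.11,4.19,8.22,8.23,18.44
14,0.60,11.5,40.00,3.62,3.62,7.00,7.00,15.48
15,0.60,11.5,35.00,3.89,3.93,7.63,7.64,16.65
16,0.60,11.5,35.00,3.86,3.90,7.57,7.58,16.71
17,0.60,11.5,35.00,3.85,3.89,7.55,7.57,17.26
18,0.60,11.5,35.00,3.85,3.91,7.57,7.60,16.87
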