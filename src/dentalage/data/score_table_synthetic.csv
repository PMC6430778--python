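sex,tooth,stage,score
M,31,0,0
M,31,A,1.04
M,31,B,1.96
M,31,C,3.03
M,31,D,4.23
M,31,E,5.46
M,31,F,6.67
M,31,G,7.8
M,31,H,9
M,32,0,0
M,32,A,0.91
M,32,B,1.83
M,32,C,2.98
M,32,D,4.32
M,32,E,5.74
M,32,F,7.17
M,32,G,8.53
M,32,H,10
M,33,0,0
M,33,A,0.73
M,33,B,1.64
M,33,C,2.86
M,33,D,4.38
M,33,E,6.08
M,33,F,7.85
M,33,G,9.58
M,33,H,11.5
M,34,0,0
M,34,A,0.56
M,34,B,1.4
M,34,C,2.65
M,34,D,4.32
M,34,E,6.28
M,34,F,8.4
M,34,G,10.55
M,34,H,13
M,35,0,0
M,35,A,0.46
M,35,B,1.27
M,35,C,2.54
M,35,D,4.34
M,35,E,6.53
M,35,F,8.99
M,35,G,11.54
M,35,H,14.5
M,36,0,0
M,36,A,1.33
M,36,B,2.8
M,36,C,4.69
M,36,D,6.96
M,36,E,9.43
M,36,F,11.94
M,36,G,14.36
M,36,H,17
M,37,0,0
M,37,A,0.51
M,37,B,1.59
M,37,C,3.49
M,37,D,6.39
M,37,E,10.15
M,37,F,14.57
M,37,G,19.32
M,37,H,25
F,31,0,0
F,31,A,1.1
F,31,B,1.99
F,31,C,3.02
F,31,D,4.15
F,31,E,5.29
F,31,F,6.4
F,31,G,7.42
F,31,H,8.5
F,32,0,0
F,32,A,0.97
F,32,B,1.9
F,32,C,3.01
F,32,D,4.28
F,32,E,5.61
F,32,F,6.93
F,32,G,8.17
F,32,H,9.5
F,33,0,0
F,33,A,0.88
F,33,B,1.88
F,33,C,3.19
F,33,D,4.79
F,33,E,6.55
F,33,F,8.35
F,33,G,10.09
F,33,H,12
F,34,0,0
F,34,A,0.68
F,34,B,1.63
F,34,C,2.98
F,34,D,4.74
F,34,E,6.76
F,34,F,8.92
F,34,G,11.08
F,34,H,13.5
F,35,0,0
F,35,A,0.55
F,35,B,1.43
F,35,C,2.77
F,35,D,4.61
F,35,E,6.8
F,35,F,9.21
F,35,G,11.67
F,35,H,14.5
F,36,0,0
F,36,A,1.47
F,36,B,2.98
F,36,C,4.86
F,36,D,7.07
F,36,E,9.43
F,36,F,11.8
F,36,G,14.06
F,36,H,16.5
F,37,0,0
F,37,A,0.63
F,37,B,1.86
F,37,C,3.93
F,37,D,6.97
F,37,E,10.83
F,37,F,15.26
F,37,G,19.96
F,37,H,25.5
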