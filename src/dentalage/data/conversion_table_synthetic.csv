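sex,dms,age
M,0,2.000
M,5,2.282
M,10,2.596
M,15,2.946
M,20,3.331
M,25,3.753
M,30,4.213
M,35,4.708
M,40,5.238
M,45,5.800
M,50,6.389
M,55,7.000
M,60,7.628
M,65,8.266
M,70,8.906
M,75,9.542
M,80,10.166
M,85,10.772
M,90,11.354
M,95,11.907
M,100,12.428
F,0,1.900
F,5,2.163
F,10,2.456
F,15,2.782
F,20,3.141
F,25,3.536
F,30,3.965
F,35,4.430
F,40,4.929
F,45,5.459
F,50,6.018
F,55,6.602
F,60,7.205
F,65,7.822
F,70,8.446
F,75,9.070
F,80,9.688
F,85,10.294
F,90,10.882
F,95,11.445
F,100,11.981
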