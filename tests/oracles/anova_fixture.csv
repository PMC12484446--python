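subject_id,group,viewing,side,score
c0,control,foveal,CH-CS,6.485
c0,control,foveal,IH-IS,4.628
c0,control,peripheral,CH-CS,9.758
c0,control,peripheral,IH-IS,6.085
c1,control,foveal,CH-CS,8.819
c1,control,foveal,IH-IS,6.122
c1,control,peripheral,CH-CS,7.661
c1,control,peripheral,IH-IS,11.184
c2,control,foveal,CH-CS,5.118
c2,control,foveal,IH-IS,5.574
c2,control,peripheral,CH-CS,8.412
c2,control,peripheral,IH-IS,4.0
c3,control,foveal,CH-CS,8.516
c3,control,foveal,IH-IS,6.171
c3,control,peripheral,CH-CS,7.373
c3,control,peripheral,IH-IS,6.166
c4,control,foveal,CH-CS,7.751
c4,control,foveal,IH-IS,5.278
c4,control,peripheral,CH-CS,11.34
c4,control,peripheral,IH-IS,8.92
c5,control,foveal,CH-CS,6.433
c5,control,foveal,IH-IS,6.542
c5,control,peripheral,CH-CS,9.119
c5,control,peripheral,IH-IS,8.1
p0,patient,foveal,CH-CS,7.635
p0,patient,foveal,IH-IS,8.635
p0,patient,peripheral,CH-CS,13.925
p0,patient,peripheral,IH-IS,10.117
p1,patient,foveal,CH-CS,6.288
p1,patient,foveal,IH-IS,4.439
p1,patient,peripheral,CH-CS,11.652
p1,patient,peripheral,IH-IS,10.071
p2,patient,foveal,CH-CS,13.743
p2,patient,foveal,IH-IS,12.151
p2,patient,peripheral,CH-CS,19.597
p2,patient,peripheral,IH-IS,17.085
p3,patient,foveal,CH-CS,6.797
p3,patient,foveal,IH-IS,8.047
p3,patient,peripheral,CH-CS,12.654
p3,patient,peripheral,IH-IS,11.467
p4,patient,foveal,CH-CS,8.955
p4,patient,foveal,IH-IS,7.493
p4,patient,peripheral,CH-CS,14.994
p4,patient,peripheral,IH-IS,10.918
p5,patient,foveal,CH-CS,10.022
p5,patient,foveal,IH-IS,6.752
p5,patient,peripheral,CH-CS,15.033
p5,patient,peripheral,IH-IS,13.013
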