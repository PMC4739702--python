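species,n,dem_mean,dem_sd,opcr3d_mean,opcr3d_sd,delta_mean,delta_sd
Cercocebus atys,7,57.41,6.932,75.71,13.798,18.30,9.133
Cercopithecus mitis,10,56.10,3.026,69.75,7.961,13.65,6.320
Colobus guereza,10,54.10,4.001,70.91,9.134,16.81,6.739
Theropithecus gelada,9,56.51,4.534,86.35,8.992,29.83,6.091
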