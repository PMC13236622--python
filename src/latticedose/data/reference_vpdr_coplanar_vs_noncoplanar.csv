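# Reference directional VPDR comparison (mean and SD, %) between coplanar
# and non-coplanar lattice radiotherapy delivery at 2.0 cm vertex separation.
# Transcribed published reference data.
diameter_cm,separation_cm,mode,direction,mean_pct,sd_pct
0.5,2,coplanar,AP,44.8,1.7
0.5,2,coplanar,LAT,44.6,1.9
0.5,2,coplanar,SI,22.0,3.5
0.5,2,noncoplanar,AP,27.8,1.5
0.5,2,noncoplanar,LAT,25.3,2.9
0.5,2,noncoplanar,SI,24.7,4.0
1.0,2,coplanar,AP,38.2,2.8
1.0,2,coplanar,LAT,37.0,2.7
1.0,2,coplanar,SI,16.9,3.4
1.0,2,noncoplanar,AP,24.8,0.5
1.0,2,noncoplanar,LAT,21.4,3.0
1.0,2,noncoplanar,SI,20.2,3.4
1.5,2,coplanar,AP,39.7,1.2
1.5,2,coplanar,LAT,40.3,1.1
1.5,2,coplanar,SI,14.5,0.8
1.5,2,noncoplanar,AP,27.6,1.5
1.5,2,noncoplanar,LAT,25.8,3.5
1.5,2,noncoplanar,SI,26.4,5.3
2.0,2,coplanar,AP,40.0,1.0
2.0,2,coplanar,LAT,39.8,1.0
2.0,2,coplanar,SI,11.4,0.7
2.0,2,noncoplanar,AP,27.2,1.9
2.0,2,noncoplanar,LAT,24.7,2.9
2.0,2,noncoplanar,SI,25.9,5.4
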