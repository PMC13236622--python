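# Reference directional VPDR values (mean and sample SD over nine profiles, %)
# for the 20 non-coplanar lattice radiotherapy phantom configurations
# (vertex diameter x edge-to-edge separation, 3x3x3 lattice).
# Transcribed published reference data.
diameter_cm,separation_cm,direction,mean_pct,sd_pct
0.5,1,AP,46.4,2.9
0.5,2,AP,27.8,1.5
0.5,3,AP,25.3,1.9
0.5,4,AP,22.1,1.4
0.5,5,AP,18.9,1.8
0.5,1,LAT,41.0,4.6
0.5,2,LAT,25.3,2.9
0.5,3,LAT,20.9,3.2
0.5,4,LAT,19.1,3.6
0.5,5,LAT,16.2,3.4
0.5,1,SI,41.9,6.3
0.5,2,SI,24.7,4.0
0.5,3,SI,22.0,4.8
0.5,4,SI,19.9,3.8
0.5,5,SI,17.5,3.6
1.0,1,AP,36.6,1.8
1.0,2,AP,24.8,0.5
1.0,3,AP,23.1,1.4
1.0,4,AP,19.9,1.9
1.0,5,AP,16.3,1.3
1.0,1,LAT,32.9,4.1
1.0,2,LAT,21.4,3.0
1.0,3,LAT,19.4,3.7
1.0,4,LAT,17.2,3.7
1.0,5,LAT,13.3,2.8
1.0,1,SI,32.7,5.5
1.0,2,SI,20.2,3.4
1.0,3,SI,18.5,3.0
1.0,4,SI,18.7,4.0
1.0,5,SI,15.5,3.0
1.5,1,AP,36.1,0.8
1.5,2,AP,27.6,1.5
1.5,3,AP,28.5,1.2
1.5,4,AP,26.5,1.7
1.5,5,AP,21.6,0.9
1.5,1,LAT,32.8,2.8
1.5,2,LAT,25.8,3.5
1.5,3,LAT,23.3,3.1
1.5,4,LAT,19.1,5.6
1.5,5,LAT,16.2,5.0
1.5,1,SI,32.2,6.4
1.5,2,SI,26.4,5.3
1.5,3,SI,23.8,6.0
1.5,4,SI,21.7,6.1
1.5,5,SI,19.3,5.5
2.0,1,AP,29.5,2.4
2.0,2,AP,27.2,1.9
2.0,3,AP,25.1,2.0
2.0,4,AP,25.6,1.8
2.0,5,AP,26.3,2.9
2.0,1,LAT,27.7,4.8
2.0,2,LAT,24.7,2.9
2.0,3,LAT,19.2,4.6
2.0,4,LAT,19.0,4.5
2.0,5,LAT,18.6,7.0
2.0,1,SI,26.8,4.5
2.0,2,SI,25.9,5.4
2.0,3,SI,21.9,5.9
2.0,4,SI,21.6,5.0
2.0,5,SI,23.4,7.0
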