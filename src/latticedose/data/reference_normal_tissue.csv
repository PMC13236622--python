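# Reference normal-tissue metrics for the non-coplanar configurations:
# mean dose inside Eval_Normal (cGy) and volume receiving >= 50% of the
# 20 Gy prescription (cm^3).  Transcribed published reference data.
diameter_cm,separation_cm,mean_dose_cgy,intersecting_volume_cm3
0.5,1,59.2,0.3
0.5,2,95.2,0.2
0.5,3,123.2,0.0
0.5,4,142.2,0.0
0.5,5,165.9,0.0
1.0,1,99.2,1.7
1.0,2,145.3,0.0
1.0,3,167.2,0.0
1.0,4,193.9,0.0
1.0,5,209.6,0.0
1.5,1,157.4,10.1
1.5,2,207.2,1.2
1.5,3,238.6,0.5
1.5,4,245.1,0.1
1.5,5,252.7,0.0
2.0,1,200.4,63.1
2.0,2,233.8,30.2
2.0,3,266.1,28.8
2.0,4,280.4,14.2
2.0,5,310.4,10.3
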