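# Reference delivery metrics for the 20 non-coplanar plans: total monitor
# units, per-arc MU for the four couch angles (0/315/45/90 deg), and the
# modulation complexity score.  Arc MU fractions are recomputed from the
# MU columns.  Transcribed published reference data.
diameter_cm,separation_cm,total_mu,mu_couch0,mu_couch315,mu_couch45,mu_couch90,mcs
0.5,1,37126.2,12045.3,7913.3,8308.3,8859.3,0.34
0.5,2,31164.0,9119.3,7842.3,7758.9,6443.5,0.28
0.5,3,31162.9,9406.5,7829.2,7594.7,6332.5,0.29
0.5,4,30853.6,8240.3,7284.0,8651.6,6677.7,0.28
0.5,5,29464.0,7776.1,7832.7,8518.2,5337.0,0.36
1.0,1,29968.4,8667.5,7752.3,7590.7,5957.9,0.36
1.0,2,20766.4,5279.4,5989.5,4458.5,5039.0,0.40
1.0,3,31644.8,7646.5,8295.6,6256.5,9446.2,0.36
1.0,4,35186.6,7929.1,8003.3,8935.5,10318.7,0.36
1.0,5,29026.1,6682.7,8925.6,8826.3,4591.5,0.40
1.5,1,39111.4,9871.9,9816.0,10551.2,8872.3,0.47
1.5,2,34690.2,8790.4,8658.9,9426.5,7814.4,0.47
1.5,3,34012.1,8786.4,8437.8,9028.6,7759.3,0.33
1.5,4,37450.4,9878.6,9012.5,9909.7,8649.6,0.32
1.5,5,33377.0,8953.7,8100.5,8601.2,7721.6,0.38
2.0,1,23992.3,6549.6,6050.4,4097.8,7294.5,0.44
2.0,2,17524.1,4710.6,4822.8,3524.0,4466.7,0.41
2.0,3,26513.2,3695.3,7395.5,9096.1,6326.3,0.31
2.0,4,30830.6,6562.6,7572.1,9816.8,6879.1,0.33
2.0,5,51487.8,16426.3,10983.4,12120.4,11957.7,0.32
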