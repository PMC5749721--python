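pair,platform,mode,zprime_mean,zprime_sd,e_percent_mean,e_percent_sd
Clv-mCh,FD,static,0.684,0.003,24.1,2.5
Clv-mR2,FD,static,-0.778,1.316,12.1,6.5
EGFP-mCh,FD,static,0.488,0.080,20.7,0.9
EGFP-mR2,FD,static,-0.725,0.212,8.5,1.0
mTFP-sRCh,FD,static,0.631,0.073,34.4,1.0
mTFP-Ven,FD,static,0.640,0.081,34.1,0.7
mTFP-YPet,FD,static,0.617,0.073,33.1,0.6
mTq2-sRCh,FD,static,0.655,0.143,30.5,1.8
mTq2-Ven,FD,static,0.437,0.047,26.9,1.5
mTq2-YPet,FD,static,0.011,0.347,33.2,4.0
Clv-mCh,TD,static,0.645,0.086,24.19,2.12
Clv-mR2,TD,static,-0.300,0.163,13.27,2.68
EGFP-mCh,TD,static,0.425,0.172,18.68,2.00
EGFP-mR2,TD,static,-0.592,0.078,10.26,1.99
mTFP-sRCh,TD,static,0.675,0.127,35.93,4.74
mTFP-Ven,TD,static,0.653,0.140,37.58,4.01
mTFP-YPet,TD,static,0.324,0.195,36.55,1.39
mTq2-sRCh,TD,static,0.610,0.021,30.86,3.35
mTq2-Ven,TD,static,0.623,0.078,32.19,2.25
mTq2-YPet,TD,static,-1.317,0.573,26.82,4.16
Clv-mCh,FD,dynamic,0.684,0.012,24.12,2.29
Clv-mR2,FD,dynamic,-0.888,1.592,12.01,7.12
EGFP-mCh,FD,dynamic,0.498,0.058,20.50,0.91
EGFP-mR2,FD,dynamic,-0.728,0.259,8.28,2.09
mTFP-sRCh,FD,dynamic,0.740,0.011,35.28,0.63
mTFP-Ven,FD,dynamic,0.583,0.042,32.99,1.06
mTFP-YPet,FD,dynamic,0.536,0.071,28.68,0.14
mTq2-sRCh,FD,dynamic,0.777,0.026,34.08,0.57
mTq2-Ven,FD,dynamic,0.395,0.081,25.78,1.52
mTq2-YPet,FD,dynamic,-0.095,0.305,26.98,3.26
Clv-mCh,TD,dynamic,0.642,0.096,23.6,2.3
Clv-mR2,TD,dynamic,-0.264,0.321,12.6,3.4
EGFP-mCh,TD,dynamic,0.420,0.183,18.7,1.7
EGFP-mR2,TD,dynamic,-0.835,0.101,8.7,1.3
mTFP-sRCh,TD,dynamic,0.482,0.168,34.8,3.1
mTFP-Ven,TD,dynamic,0.604,0.127,37.2,4.6
mTFP-YPet,TD,dynamic,0.192,0.252,37.1,1.0
mTq2-sRCh,TD,dynamic,0.552,0.049,29.6,1.3
mTq2-Ven,TD,dynamic,0.557,0.091,30.8,1.5
mTq2-YPet,TD,dynamic,-1.354,0.561,27.4,6.4
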