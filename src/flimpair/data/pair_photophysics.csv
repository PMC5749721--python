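pair,donor,acceptor,qy_donor,J_nm4_M_cm,r0_nm
Clv-mCh,Clv,mCh,0.76,2.50E+15,5.18
Clv-mR2,Clv,mR2,0.76,4.51E+15,5.71
EGFP-mCh,EGFP,mCh,0.60,1.94E+15,4.77
EGFP-mR2,EGFP,mR2,0.60,3.61E+15,5.29
mTFP-sRCh,mTFP1,sRCh,0.85,3.19E+15,5.50
mTFP-Ven,mTFP1,Ven,0.85,2.56E+15,5.30
mTFP-YPet,mTFP1,YPet,0.85,2.89E+15,5.40
mTq2-sRCh,mTq2,sRCh,0.93,2.54E+15,5.37
mTq2-Ven,mTq2,Ven,0.93,2.04E+15,5.18
mTq2-YPet,mTq2,YPet,0.93,2.30E+15,5.28
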