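name,role,ex_nm,em_nm,tau_ns,qy,eps_e3
mTFP1,donor,462,492,2.8,0.85,
mTq2,donor,437,474,4.0,0.93,
EGFP,donor,489,509,2.4,0.6,
Clv,donor,505,515,3.2,0.76,
YPet,acceptor,517,530,,,104
Ven,acceptor,515,528,,,92.2
sRCh,acceptor,510,538,,,115
mCh,acceptor,587,610,,,72
mR2,acceptor,559,600,,,113
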