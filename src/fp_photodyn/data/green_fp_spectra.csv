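name,eps_peak,eps_ex,qy,lambda_ab,lambda_em
StayGold,159000,105000,0.93,496,505
EGFP,51000,51000,0.71,488,509
SiriusGFP,54000,35000,0.19,502,516
mClover3,99000,52000,0.84,505,518
mNeonGreen,112000,64000,0.87,505,518
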