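Country,Cross,Trait,Avg_h2,Sd_h2,Avg_R,Sd_R,Avg_PA,Sd_PA
France,BoxBo,FW,0.22,0.22,0.34,0.28,0.42,0.39
France,BC2,TA,0.63,0.26,0.87,0.03,0.76,0.08
France,BC2,FW,0.24,0.03,0.25,0.03,0.54,0.06
France,BC2,SC,0.08,0.03,0.18,0.03,0.78,0.11
Italy,BxO,TA,0.34,0.07,0.44,0.04,0.52,0.09
Italy,BxO,FW,0.78,0.16,0.83,0.02,0.84,0.04
Italy,BxO,SC,0.63,0.14,0.70,0.03,0.69,0.06
Italy,PxF,TA,0.30,0.00,0.38,0.00,0.50,0.07
Italy,PxF,FW,0.33,0.15,0.45,0.16,0.49,0.24
Italy,PxF,SC,0.53,0.00,0.64,0.00,0.75,0.05
Italy,MxR028,TA,0.39,0.00,0.49,0.00,0.66,0.11
Italy,MxR028,FW,0.42,0.16,0.55,0.09,0.71,0.11
Italy,MxR028,SC,0.46,0.01,0.58,0.00,0.77,0.08
Italy,WxBy,FW,0.47,0.08,0.58,0.06,0.58,0.12
Spain,BbxNl,TA,0.83,0.02,0.83,0.02,0.83,0.04
Spain,BbxNl,FW,0.27,0.20,0.78,0.05,0.63,0.11
Spain,BbxNl,SC,0.86,0.04,0.89,0.03,0.67,0.09
Spain,BtxAk,TA,0.43,0.12,0.46,0.07,0.59,0.10
Spain,BtxAk,FW,0.29,0.21,0.57,0.10,0.70,0.17
Spain,BtxAk,SC,0.62,0.13,0.65,0.03,0.72,0.07
Spain,BtxNr,TA,0.50,0.08,0.65,0.04,0.60,0.11
Spain,BtxNr,FW,0.29,0.18,0.45,0.10,0.39,0.20
Spain,BtxNr,SC,0.57,0.11,0.71,0.04,0.68,0.13
Spain,T1E,TA,0.67,0.08,0.74,0.07,0.79,0.07
Spain,T1E,FW,0.21,0.20,0.54,0.20,0.53,0.29
Spain,T1E,SC,0.41,0.07,0.54,0.06,0.75,0.09
Spain,TxE,TA,0.67,0.13,0.78,0.08,0.58,0.19
Spain,TxE,FW,0.36,0.39,0.86,0.06,0.81,0.13
Spain,TxE,SC,0.21,0.27,0.79,0.08,0.66,0.16
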