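gene,patient_id,mlpa_call,snp_cbs_call,snp_manual_call,category,risk_mlpa,risk_snp_cbs,risk_snp_manual
IKZF1,19732,deletion ex4-7,normal,deletion ex4-7,iii,IR/PR,IR/PR,IR/PR
IKZF1,20035,deletion ex2-7,normal,deletion ex2-7,iii,IR/PR,GR,IR/PR
IKZF1,20753,deletion ex4-8,normal,deletion ex4-8,iii,IR/PR,IR/PR,IR/PR
IKZF1,22964,deletion ex4-7,normal,deletion ex4-7,iii,IR/PR,IR/PR,IR/PR
IKZF1,22388,deletion ex4-7,normal,deletion ex4-8,iii,IR/PR,GR,IR/PR
IKZF1,10054,deletion ex4-7,normal,deletion ex4-7,iii,IR/PR,GR,IR/PR
IKZF1,10062,deletion ex4-7,normal,deletion ex4-8,iii,IR/PR,IR/PR,IR/PR
IKZF1,11560,deletion ex4-7,normal,normal,iv,IR/PR,GR,GR
IKZF1,11741,deletion ex4-7,normal,deletion ex4-7,iii,IR/PR,GR,IR/PR
ETV6,8947,deletion,normal,normal,iv,IR/PR,IR/PR,IR/PR
CDKN2A,20753,deletion,normal,normal,i,IR/PR,IR/PR,IR/PR
CDKN2A,22572,deletion,normal,normal,i,IR/PR,GR,GR
CDKN2A,22689,deletion,normal,normal,i,IR/PR,IR/PR,IR/PR
CDKN2B,21324,deletion,normal,normal,ii,IR/PR,IR/PR,IR/PR
CDKN2B,22572,deletion,normal,normal,ii,IR/PR,GR,GR
RB1,10958,deletion,normal,normal,iv,IR/PR,GR,GR
RB1,20874,gain,normal,normal,iv,IR/PR,IR/PR,IR/PR
EBF1,3278,normal,loss,loss,v,IR/PR,IR/PR,IR/PR
PAX5,9262,gain,normal,normal,iv,IR/PR,IR/PR,IR/PR
PAX5,10077,gain,normal,gain,iii,GR,GR,GR
PAX5,10442,gain,normal,normal,iv,IR/PR,IR/PR,IR/PR
PAX5,20515,normal,loss,loss,v,GR,GR,GR
PAX5,11957,normal,loss,loss,v,GR,GR,GR
PAR1,11403,rearrangement,normal,normal,i,IR/PR,GR,GR
PAR1,21819,rearrangement,normal,normal,i,IR/PR,IR/PR,IR/PR
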