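gene,mlpa,snp_cbs,snp_manual,count,category
IKZF1,normal,normal,normal,113,
IKZF1,abnormal,normal,normal,1,iv
IKZF1,abnormal,abnormal,abnormal,21,
IKZF1,abnormal,normal,abnormal,8,iii
ETV6,normal,normal,normal,120,
ETV6,abnormal,normal,normal,1,iv
ETV6,abnormal,abnormal,abnormal,22,
CDKN2A,normal,normal,normal,83,
CDKN2A,abnormal,normal,normal,3,i
CDKN2A,abnormal,abnormal,abnormal,57,
CDKN2B,normal,normal,normal,83,
CDKN2B,abnormal,normal,normal,2,ii
CDKN2B,abnormal,abnormal,abnormal,58,
RB1,normal,normal,normal,131,
RB1,abnormal,normal,normal,2,iv
RB1,abnormal,abnormal,abnormal,10,
BTG1,normal,normal,normal,142,
BTG1,abnormal,abnormal,abnormal,1,
EBF1,normal,normal,normal,133,
EBF1,normal,abnormal,abnormal,1,v
EBF1,abnormal,abnormal,abnormal,9,
PAX5,normal,normal,normal,95,
PAX5,abnormal,normal,normal,2,iv
PAX5,normal,abnormal,abnormal,2,v
PAX5,abnormal,abnormal,abnormal,43,
PAX5,abnormal,normal,abnormal,1,iii
PAR1,normal,normal,normal,138,
PAR1,abnormal,normal,normal,2,i
PAR1,abnormal,abnormal,abnormal,3,
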