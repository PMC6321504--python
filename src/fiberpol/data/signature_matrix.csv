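name,gene,diagnosis,group,aliases,kind,ca_sensitivity,tpm_stiffness_high,tpm_stiffness_low,tn_shift_high,tn_shift_low,s1_shift_high,s1_shift_low,actin_on_tpm_high,actin_on_tpm_low,actin_on_s1_high,actin_on_s1_low,strong_binding_high,strong_binding_low,strong_binding_atp_high,strong_binding_atp_low
E41K,TPM2,NM;Cap,Cap,,row,down,down,down,down,norm,down,up,norm,up,down,up,down,down,up,up
R90P,TPM3,CFTD,CFTD,,row,up,up,up,up,up,down,up,down,up,down,down,up,up,down,up
R91G,TPM2,DA,DA,,row,up,down,down,norm,norm,up,up,down,down,down,up,up,up,down,up
E117K,TPM2,NM;CFTD;DA,NM,,row,down,up,up,,,,,,,,,down,down,down,down
E139X,TPM2,Cap;CFTD,Cap,E139del,row,up,down,down,up,up,up,up,up,down,up,down,down,up,down,up
Q147P,TPM2,Cap;NM,Cap,,row,up,up,up,up,up,down,up,down,up,down,down,down,up,down,up
E150A,TPM3,Cap,CFTD,,row,up,down,down,down,up,up,up,up,up,up,up,up,up,down,up
A155T,TPM3,NM,Cap,,row,up,down,down,norm,norm,up,up,norm,norm,up,up,down,up,down,up
A155T,TPM1,,unassigned,,row,,down,down,up,up,down,up,up,up,down,up,down,up,down,up
R167H,TPM1,,unassigned,,row,,up,up,down,up,down,norm,down,up,up,up,down,down,down,down
K168E,TPM1,,unassigned,,row,,up,up,norm,norm,down,down,down,down,norm,down,down,up,down,up
E173A,TPM3,CFTD,CFTD,,row,up,down,down,up,up,up,up,up,up,up,up,up,up,up,up
CFTD-consensus,,,CFTD,,consensus,,,,,,,,,,,,up,up,,
Cap-consensus,,,Cap,,consensus,,,,,,,,,,,,down,,,up
NM-consensus,,,NM,,consensus,,,,,,,,,,,,down,down,,
DA-consensus,,,DA,,consensus,,,,norm,norm,,,,,,,up,,,
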