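smiles,target_id,target_is_kinase,activity_type,pchembl
c1ccc2ncncc2c1,KIN1,true,IC50,6.5
Cc1ccccc1,KIN1,true,IC50,6.0
CCCCO,KIN2,true,Ki,6.01
c1ccncc1,GPCR1,false,IC50,9.0
CCN,KIN1,true,EC50,7.0
c1ccc2[nH]ccc2c1,KIN3,true,Kd,7.2
CCO,KIN2,true,IC50,8.0
c1ccc2ncncc2c1,KIN2,true,Ki,7.0
,KIN1,true,IC50,7.0
Cc1ccccc1,KIN3,true,Ki,5.2
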