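name,lo,hi,assignment
glycogen_480,480,480,other
adenosine_720,720,720,nucleic_acid
cytc_750,746,750,other
trp_752_760,752,760,protein
rna_811,811,811,nucleic_acid
carb_877,877,877,lipid
phe_1003,1003,1003,protein
po2_1081,1081,1081,nucleic_acid
na_bases_1090,1090,1095,nucleic_acid
na_bases_1180,1180,1180,nucleic_acid
amide_iii_beta_1235,1235,1240,protein
lipid_ch2_1297,1295,1300,lipid
amide_iii_1337,1337,1337,protein
ch_def_1449,1449,1452,lipid
amide_ii_1580,1580,1580,protein
cytc_1582,1582,1582,other
retinoic_1605,1605,1605,other
amide_i_1654,1654,1655,protein
lipid_cc_1660,1660,1660,lipid
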