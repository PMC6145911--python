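gene_symbol,pct_alp,p_bound
H2-Ob,231.79,0.05
Ifna9,205.22,0.05
Icam5,193.19,0.01
H2-DMa,192.48,0.01
Il13ra2,187.73,0.05
Hgfac,12.52,0.001
Ifna13,14.40,0.001
Idi1,15.06,0.001
Icos,17.07,0.001
Ssh1,18.38,0.001
Hmbs,19.25,0.001
Ube2k,19.83,0.001
Igfbp1,20.25,0.001
Glipr1,21.09,0.001
Hspa5,21.38,0.001
Hip1,21.74,0.001
Ifi30,22.19,0.001
Herpud1,22.43,0.001
Herc2,22.60,0.001
Golga5,22.68,0.001
Hdac7,22.85,0.001
Gnmt,22.92,0.001
Hal,23.37,0.001
Hmga2,23.53,0.001
Hcrtr1,25.64,0.001
Hey2,26.08,0.001
Hmgn2,27.29,0.001
Hspb1,27.62,0.001
Sap30bp,28.38,0.001
Hrc,28.65,0.01
Ifngr2,29.00,0.001
Hus1,29.61,0.001
Hoxb5,29.71,0.001
Ifit3,29.78,0.001
Il11,29.79,0.001
Hrasls,29.82,0.01
Hat1,30.15,0.01
Golgb1,30.26,0.001
Lilrb4,30.49,0.001
Hp,30.75,0.001
Hfe,30.79,0.001
Hcn2,30.92,0.001
Herc1,31.25,0.001
Hrg,31.67,0.001
Hdac2,31.72,0.001
H2-T23,31.89,0.001
Hoxc4,31.92,0.001
Icam1,33.13,0.001
Hpcal1,33.40,0.001
Ifi204,34.07,0.01
Hivep2,34.29,0.01
Ifnar1,34.37,0.001
Hps3,35.06,0.001
Ifit2,36.49,0.001
Hsf2,37.11,0.01
Hdac3,37.29,0.001
Ifna4,38.04,0.001
Hoxd12,38.15,0.01
Gpr135,38.43,0.001
Hgf,38.54,0.001
Hdac11,38.70,0.001
Hsd11b2,38.72,0.01
Glo1,38.83,0.001
Hnf4g,39.32,0.001
Hesx1,39.62,0.01
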