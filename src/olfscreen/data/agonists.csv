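id,name,ec50_uM,class,encoding,flag
A1,4-isobutylphenol,13.0,1,literature-odorant,ok
A2,4-cyclohexylphenol,22.0,1,literature-odorant,ok
A3,4-(2-methylbutyl)phenol,38.0,1,reconstructed,ok
B1,4-tert-butylphenol,64.0,1,literature-odorant,ok
A4,2-methoxy-4-pentylphenol,7.0,2,reconstructed,ok
A5,4-cyclopentyl-2-methoxyphenol,120.0,2,reconstructed,ok
B2,eugenol,29.0,2,literature-odorant,ok
B3,isoeugenol,12.0,2,literature-odorant,ok
B4,4-propylguaiacol,45.0,2,literature-odorant,ok
B5,4-isobutylguaiacol,80.0,2,literature-odorant,ok
B6,4-prenylguaiacol,160.0,2,literature-odorant,ok
B7,methoxyeugenol,200.0,2,literature-odorant,ok
B8,2-methoxy-4-(4-methylcyclohex-3-en-1-yl)phenol,240.0,2,reconstructed,ok
A6,4-ethoxy-3-methoxybenzaldehyde,40.0,3,reconstructed,ok
A7,3-ethoxy-4-methoxybenzaldehyde,130.0,3,reconstructed,ambiguous-isomer
A8,"2,4-dimethoxybenzaldehyde",220.0,3,reconstructed,ok
B9,4-anisaldehyde,26.0,3,literature-odorant,ok
B10,veratraldehyde,65.0,3,literature-odorant,ok
B11,4-ethoxybenzaldehyde,90.0,3,literature-odorant,ok
B12,"3,4,5-trimethoxybenzaldehyde",180.0,3,literature-odorant,ok
B13,4-methoxy-3-methylbenzaldehyde,270.0,3,literature-odorant,ok
A9,4'-hydroxypropiophenone,4.0,4,literature-odorant,ok
A10,acetosyringone,9.0,4,literature-odorant,ok
A11,4'-hydroxyacetophenone,15.0,4,literature-odorant,ok
A12,4-hydroxybenzaldehyde,22.0,4,literature-odorant,ok
A13,isovanillin,30.0,4,literature-odorant,ok
A14,4-hydroxy-2-methoxybenzaldehyde,200.0,4,reconstructed,ambiguous-isomer
A15,2-hydroxy-5-methoxybenzaldehyde,280.0,4,reconstructed,ambiguous-isomer
B14,vanillin,41.0,4,literature-odorant,ok
B15,ethylvanillin,55.0,4,literature-odorant,ok
B16,acetovanillone,70.0,4,literature-odorant,ok
B17,zingerone,85.0,4,literature-odorant,ok
B18,syringaldehyde,100.0,4,literature-odorant,ok
B19,vanillyl alcohol,350.0,4,literature-odorant,ok
B20,o-vanillin,440.0,4,literature-odorant,ok
B21,4'-hydroxy-3'-methylacetophenone,550.0,4,reconstructed,ambiguous-isomer
B22,raspberry ketone,660.0,4,literature-odorant,ok
A16,4-propylcyclohexanone,36.0,5,literature-odorant,ok
A17,4-isopropylcyclohexanone,63.0,5,literature-odorant,ok
B23,4-tert-butylcyclohexanone,45.0,5,literature-odorant,ok
B24,4-sec-butylcyclohexanone,55.0,5,literature-odorant,ok
B25,rose oxide,630.0,6,literature-odorant,ok
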