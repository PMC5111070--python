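name,both_sexes,total_area_km2,ajo_km2,apjo_km2,good_area_km2,pop,pop_lo,pop_hi
Green Corridor,True,14535,13430,1105,13430,52,38,64
Upper Parana-Paranapanema,True,6724,5343,1380,5343,47,26,67
Serra do Mar,True,13547,7315,6232,7315,14,6,24
Mbaracayu,True,4086,2643,1443,2643,12,8,18
Linhares-Sooretama,True,503,503,0,230,10,9,14
Rio Doce,True,1407,1113,294,1113,,,
Serra do Mar Norte,True,3915,1006,2908,1006,,,
San Rafael,False,2941,1958,983,1958,,,
Itaipu,False,2258,1460,798,1460,,,
Serra dos Orgaos,False,1578,827,751,827,,,
Itatiaia,False,1336,1000,336,1000,,,
Campos do Jordao,False,539,536,3,536,,,
Small fragments,False,877,690,187,0,,,
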