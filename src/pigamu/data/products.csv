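product_name,form,pack_size,ingredient,strength_mg_per_unit,declared_in_iu
apramycin-soluble-1kg,water_soluble,1000,apramycin,552,false
amoxicillin-soluble-1kg,water_soluble,1000,amoxicillin,697,false
tylosin-soluble-1.1kg,water_soluble,1100,tylosin,880,false
sulfatrim-soluble-1kg,water_soluble,1000,sulfadiazine,400,false
sulfatrim-soluble-1kg,water_soluble,1000,trimethoprim,80,false
colistin-soluble-1kg,water_soluble,1000,colistin,2000000,true
lincospectin-soluble-150g,water_soluble,150,lincomycin,222,false
lincospectin-soluble-150g,water_soluble,150,spectinomycin,444.7,false
ctc-topdress-5kg,top_dressing,5000,chlortetracycline,100,false
amoxicillin-oral-paste-100g,oral_dose,100,amoxicillin,100,false
spectinomycin-oral-100ml,oral_dose,100,spectinomycin,50,false
amoxicillin-la-inj-100ml,injectable,100,amoxicillin,150,false
procaine-penicillin-inj-100ml,injectable,100,benzylpenicillin,300,false
penstrep-inj-100ml,injectable,100,benzylpenicillin,200,false
penstrep-inj-100ml,injectable,100,streptomycin,250,false
enrofloxacin-inj-100ml,injectable,100,enrofloxacin,100,false
marbofloxacin-inj-100ml,injectable,100,marbofloxacin,100,false
ceftiofur-inj-100ml,injectable,100,ceftiofur,50,false
tulathromycin-inj-50ml,injectable,50,tulathromycin,100,false
tildipirosin-inj-50ml,injectable,50,tildipirosin,40,false
florfenicol-inj-100ml,injectable,100,florfenicol,300,false
tiamulin-inj-100ml,injectable,100,tiamulin,200,false
tylosin-inj-100ml,injectable,100,tylosin,200,false
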