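name,antimicrobial_class,dddvet_mg_per_kg,la_dose_mg_per_kg,la_factor,conversion_factor,iu_per_mg,ema_category,who_hpcia,source
chlortetracycline,tetracyclines,20,,1.0,1.0,,D,false,placeholder
sulfadiazine,potentiated_sulphonamides,25,,1.0,1.0,,D,false,placeholder
trimethoprim,potentiated_sulphonamides,5,,1.0,1.0,,D,false,placeholder
tylosin,macrolides,15,,1.0,1.0,,C,true,placeholder
tilmicosin,macrolides,16,,1.0,1.0,,C,true,placeholder
tulathromycin,macrolides,,2.5,5.0,1.0,,C,true,placeholder
tildipirosin,macrolides,,4.0,9.0,1.0,,C,true,placeholder
amoxicillin,penicillins,15,,1.0,1.0,,D,false,placeholder
benzylpenicillin,penicillins,10,,1.0,0.6,,D,false,placeholder
streptomycin,aminoglycosides,25,,1.0,0.8,,C,false,placeholder
apramycin,aminoglycosides,20,,1.0,1.0,,C,false,placeholder
spectinomycin,aminocyclitols,30,,1.0,1.0,,C,false,placeholder
lincomycin,lincosamides,10,,1.0,1.0,,C,false,placeholder
florfenicol,amphenicols,15,,1.0,1.0,,C,false,placeholder
colistin,polymyxins,5,,1.0,1.0,30000,B,true,placeholder
enrofloxacin,fluoroquinolones,5,,1.0,1.0,,B,true,placeholder
marbofloxacin,fluoroquinolones,2,,1.0,1.0,,B,true,stated
ceftiofur,cephalosporins_3_4,3,,1.0,1.0,,B,true,placeholder
tiamulin,pleuromutilins,10,,1.0,1.0,,C,false,placeholder
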