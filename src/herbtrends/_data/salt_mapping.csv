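label,ai,mass_factor
"2,4-d, dimethylamine salt","2,4-d",1.0
"2,4-d, diethanolamine salt","2,4-d",1.0
"2,4-d, isopropylamine salt","2,4-d",1.0
"2,4-d, triisopropanolamine salt","2,4-d",1.0
"2,4-d, sodium salt","2,4-d",1.0
"2,4-d, choline salt","2,4-d",1.0
"2,4-d, 2-ethylhexyl ester","2,4-d",1.0
"2,4-d, butoxyethyl ester","2,4-d",1.0
"glyphosate, isopropylamine salt",glyphosate,1.0
"glyphosate, potassium salt",glyphosate,1.0
"glyphosate, ammonium salt",glyphosate,1.0
"glyphosate, diammonium salt",glyphosate,1.0
"glyphosate, dimethylamine salt",glyphosate,1.0
"glyphosate, sesquisodium salt",glyphosate,1.0
"glyphosate, trimesium salt",glyphosate,1.0
"dicamba, diglycolamine salt",dicamba,1.0
"dicamba, dimethylamine salt",dicamba,1.0
"dicamba, sodium salt",dicamba,1.0
"dicamba, potassium salt",dicamba,1.0
"mcpa, dimethylamine salt",mcpa,1.0
"mcpa, 2-ethylhexyl ester",mcpa,1.0
"mcpa, sodium salt",mcpa,1.0
"clopyralid, monoethanolamine salt",clopyralid,1.0
"clopyralid, triethylamine salt",clopyralid,1.0
"triclopyr, butoxyethyl ester",triclopyr,1.0
"triclopyr, triethylamine salt",triclopyr,1.0
"paraquat dichloride",paraquat,1.0
"diquat dibromide",diquat,1.0
"glufosinate-ammonium",glufosinate,1.0
"fluroxypyr 1-methylheptyl ester",fluroxypyr,1.0
"bromoxynil octanoate",bromoxynil,1.0
"bromoxynil heptanoate",bromoxynil,1.0
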