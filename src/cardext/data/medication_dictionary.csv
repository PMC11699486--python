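name,class
aspirin,aspirin
acetylsalicylic acid,aspirin
ascard,aspirin
loprin,aspirin
disprin,aspirin
atorvastatin,statin
rosuvastatin,statin
simvastatin,statin
lipitor,statin
lipiget,statin
crestor,statin
clopidogrel,clopidogrel
plavix,clopidogrel
lowplat,clopidogrel
noclot,clopidogrel
metoprolol,beta_blocker
atenolol,beta_blocker
carvedilol,beta_blocker
bisoprolol,beta_blocker
propranolol,beta_blocker
betaloc,beta_blocker
merol,beta_blocker
tenormin,beta_blocker
inderal,beta_blocker
concor,beta_blocker
metformin,antidiabetic
gliclazide,antidiabetic
glimepiride,antidiabetic
sitagliptin,antidiabetic
insulin,antidiabetic
glucophage,antidiabetic
diamicron,antidiabetic
getryl,antidiabetic
mixtard,antidiabetic
humulin,antidiabetic
enalapril,ace_inhibitor
lisinopril,ace_inhibitor
ramipril,ace_inhibitor
captopril,ace_inhibitor
renitec,ace_inhibitor
zestril,ace_inhibitor
capoten,ace_inhibitor
losartan,arb
valsartan,arb
telmisartan,arb
candesartan,arb
eziday,arb
telsan,arb
cozaar,arb
diovan,arb
aspirin clopidogrel,aspirin_clopidogrel_combo
coplavix,aspirin_clopidogrel_combo
asclop,aspirin_clopidogrel_combo
ticagrelor,ticagrelor
brilinta,ticagrelor
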