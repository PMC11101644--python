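source,sign,target,kind,compartment
TGFB,activation,TGFBR,complex,membrane
TGFBR,activation,SMAD,complex,nucleus
SMAD,activation,SNAIL,protein,nucleus
TGFBR,activation,AKT,protein,cytoplasm
AKT,inhibition,GSK3B,protein,cytoplasm
GSK3B,inhibition,SNAIL,protein,nucleus
AKT,activation,TWIST,protein,nucleus
TWIST,activation,AKT,protein,cytoplasm
AKT,activation,NFKB,protein,nucleus
NFKB,activation,SNAIL,protein,nucleus
NFKB,activation,NKILA,rna,cytoplasm
NKILA,inhibition,NFKB,protein,nucleus
SNAIL,inhibition,Ecadherin,protein,membrane
ZEB,inhibition,Ecadherin,protein,membrane
SNAIL,inhibition,ZO1,protein,membrane
SNAIL,inhibition,miR34,rna,cytoplasm
miR34,inhibition,SNAIL,protein,nucleus
SNAIL,activation,ZEB,protein,nucleus
ZEB,inhibition,miR200,rna,cytoplasm
miR200,inhibition,ZEB,protein,nucleus
SNAIL,inhibition,miR200,rna,cytoplasm
ZEB,inhibition,GRHL2,protein,nucleus
GRHL2,inhibition,ZEB,protein,nucleus
SNAIL,inhibition,GRHL2,protein,nucleus
ZEB,inhibition,OVOL2,protein,nucleus
OVOL2,inhibition,ZEB,protein,nucleus
SNAIL,inhibition,OVOL2,protein,nucleus
SNAIL,activation,Goosecoid,protein,nucleus
ZEB,activation,Ncadherin,protein,membrane
TWIST,activation,Ncadherin,protein,membrane
AKT,activation,MDM2,protein,nucleus
MDM2,inhibition,p53,protein,nucleus
p53,activation,miR34,rna,cytoplasm
SNAIL,activation,EMT,phenotype,cytoplasm
ZEB,activation,EMT,phenotype,cytoplasm
TWIST,activation,EMT,phenotype,cytoplasm
Ecadherin,inhibition,EMT,phenotype,cytoplasm
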