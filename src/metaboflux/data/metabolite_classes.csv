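metabolite,class
ATP,redox/energetics
ADP,redox/energetics
AMP,redox/energetics
PCr,redox/energetics
creatine,redox/energetics
NAD,redox/energetics
NADH,redox/energetics
TAN,redox/energetics
PCr/ATP,redox/energetics
NAD/NADH,redox/energetics
succinate,TCA
fumarate,TCA
citrate,TCA
malate,TCA
succinate/fumarate,TCA
glucose,carbohydrate
glycogen,carbohydrate
lactate,carbohydrate
myo-inositol,carbohydrate
acetate,lipid
acetylcarnitine,lipid
carnitine,lipid
choline,lipid
phosphocholine,lipid
alanine,amino acid
glycine,amino acid
valine,amino acid
leucine,amino acid
isoleucine,amino acid
glutamate,amino acid
glutamine,amino acid
aspartate,amino acid
taurine,amino acid
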