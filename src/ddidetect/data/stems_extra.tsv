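# supplementary stem lexicon (normalized), mainly German compound parts
proton
pumpe
inhibitor
hemmer
herz
infarkt
knochen
dichte
mangel
risiko
schutz
therapie
fraktur
wirbel
magen
darm
niere
leber
lunge
alter
saeure
messung
wert
score
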