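taxon_code,core_id,n_fragments
alsebl,A,1
alsebl,C,5
alsebl,F,2
alsebl,G,5
alsebl,H,6
alsebl,J,1
alsebl,K,1
arec1,C,1
beilpe,F,3
beilpe,I,3
beilpe,L,2
bign1,K,3
bign2,A,1
bign3,K,1
brosal,C,1
brosal,H,2
burs1,H,1
cela1,A,1
chry1,H,2
chry1,L,1
chry2,K,1
cocc1,K,1
couscu,F,1
couscu,G,2
couscu,L,1
faba1,J,1
faraoc,F,1
guapst,F,1
gustsu,H,1
gustsu,L,3
hybapr,B,1
hybapr,H,2
jacaco,C,1
malp1,I,3
poutre,G,1
prottn,H,1
quaras,A,1
quaras,B,1
quaras,E,10
quaras,F,3
quaras,H,5
quaras,I,7
quaras,J,4
sapi1,F,1
sapi1,G,4
tabegu,D,1
tabear,B,2
tachve,I,3
tetrpa,C,1
tricgi,B,1
trictu,C,1
trictu,D,1
trictu,J,4
trictu,K,2
ulma1,D,1
virose,H,2
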