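sex,age,parameter,percentile,value
F,7,SS,3,12
F,7,SS,10,17
F,7,SS,25,22
F,7,SS,50,27
F,7,SS,75,33
F,7,SS,90,39
F,7,SS,97,44
F,7,LL,3,13
F,7,LL,10,18
F,7,LL,25,23
F,7,LL,50,29
F,7,LL,75,37
F,7,LL,90,45
F,7,LL,97,52
F,7,TK,3,23
F,7,TK,10,28
F,7,TK,25,35
F,7,TK,50,42
F,7,TK,75,48
F,7,TK,90,55
F,7,TK,97,62
F,7,CI,3,14
F,7,CI,10,18
F,7,CI,25,22
F,7,CI,50,27
F,7,CI,75,32
F,7,CI,90,36
F,7,CI,97,41
F,7,HP,3,45
F,7,HP,10,49
F,7,HP,25,54
F,7,HP,50,58
F,7,HP,75,63
F,7,HP,90,66
F,7,HP,97,71
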