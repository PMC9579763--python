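stage,base_ma,top_ma
Lochkovian,419.2,410.8
Pragian,410.8,407.6
Emsian,407.6,393.3
Eifelian,393.3,387.7
Givetian,387.7,382.7
Frasnian,382.7,372.2
Famennian,372.2,358.9
Tournaisian,358.9,346.7
Visean,346.7,330.9
Serpukhovian,330.9,323.2
Bashkirian,323.2,315.2
Moscovian,315.2,307.0
Kasimovian,307.0,303.7
Gzhelian,303.7,298.9
Asselian,298.9,295.0
Sakmarian,295.0,290.1
Artinskian,290.1,283.5
Kungurian,283.5,272.95
Roadian,272.95,268.8
Wordian,268.8,265.1
Capitanian,265.1,259.1
Wuchiapingian,259.1,254.14
Changhsingian,254.14,251.902
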