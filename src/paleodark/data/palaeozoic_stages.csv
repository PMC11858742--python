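name,max_ma,min_ma,level
Fortunian,538.8,529.0,stage
Cambrian Stage 2,529.0,521.0,stage
Cambrian Stage 3,521.0,514.5,stage
Cambrian Stage 4,514.5,509.0,stage
Wuliuan,509.0,504.5,stage
Drumian,504.5,500.5,stage
Guzhangian,500.5,497.0,stage
Paibian,497.0,494.0,stage
Jiangshanian,494.0,489.5,stage
Cambrian Stage 10,489.5,485.4,stage
Tremadocian,485.4,477.7,stage
Floian,477.7,470.0,stage
Dapingian,470.0,467.3,stage
Darriwilian,467.3,458.4,stage
Sandbian,458.4,453.0,stage
Katian,453.0,445.2,stage
Hirnantian,445.2,443.8,stage
Rhuddanian,443.8,440.8,stage
Aeronian,440.8,438.5,stage
Telychian,438.5,433.4,stage
Sheinwoodian,433.4,430.5,stage
Homerian,430.5,427.4,stage
Gorstian,427.4,425.6,stage
Ludfordian,425.6,423.0,stage
Pridoli,423.0,419.2,stage
Lochkovian,419.2,410.8,stage
Pragian,410.8,407.6,stage
Emsian,407.6,393.3,stage
Eifelian,393.3,387.7,stage
Givetian,387.7,382.7,stage
Frasnian,382.7,372.2,stage
Famennian,372.2,358.9,stage
Tournaisian,358.9,346.7,stage
Visean,346.7,330.9,stage
Serpukhovian,330.9,323.2,stage
Bashkirian,323.2,315.2,stage
Moscovian,315.2,307.0,stage
Kasimovian,307.0,303.7,stage
Gzhelian,303.7,298.9,stage
Asselian,298.9,293.52,stage
Sakmarian,293.52,290.1,stage
Artinskian,290.1,283.5,stage
Kungurian,283.5,273.01,stage
Roadian,273.01,266.9,stage
Wordian,266.9,264.28,stage
Capitanian,264.28,259.51,stage
Wuchiapingian,259.51,254.14,stage
Changhsingian,254.14,251.902,stage
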