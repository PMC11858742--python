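name,max_ma,min_ma,level
Cambrian,538.8,485.4,sub_period
Ordovician,485.4,443.8,sub_period
Silurian,443.8,419.2,sub_period
Devonian,419.2,358.9,sub_period
Mississippian,358.9,323.2,sub_period
Pennsylvanian,323.2,298.9,sub_period
Permian,298.9,251.902,sub_period
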