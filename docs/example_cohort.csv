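# strain_label=example
# n0=3
# stage_order=egg,larva,pupa,female,male
id,sex,fate,death_stage,emergence_day,death_day,dur_egg,dur_larva,dur_pupa
f1,female,died_adult,female,12,17,3,5,4
m1,male,died_adult,male,13,20,3,6,4
d1,unknown,died_preadult,larva,,5,3,,
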