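id,age_day,eggs
f1,12,40
f1,13,25
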