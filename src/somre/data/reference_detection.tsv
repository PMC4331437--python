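family	detected	annotated	pct
L1Hs	817	1528	53.5
AluYa5	2933	3918	74.9
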