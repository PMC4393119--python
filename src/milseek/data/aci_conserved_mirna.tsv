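lib	name	sequence	reads
F	miR-26	UUCAAGUAAUCCAGGAUAGG	2
B	miR-27d	UUCACAGUGGCUAAGUUC	6
M	miR-545	AUCAACAAACAUUUAUUGUGUG	4
B	miR-574	UGAGUGUGUGUGUGUGAGUGUGU	20
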