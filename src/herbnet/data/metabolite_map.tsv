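parent_id	metabolite_id	mechanism
M_28	M_29	esterase hydrolysis (colonic microflora)
M_04	M_05	glycosidase hydrolysis (colonic microflora)
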