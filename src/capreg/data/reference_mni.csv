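label,x,y,z
Nz,0.0,86.0,-40.0
AL,-84.0,-12.0,-48.0
AR,84.0,-12.0,-48.0
Cz,0.0,-10.0,98.0
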