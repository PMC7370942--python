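label,dx,dy,dz
Nz,0.0,1.0,-0.20
AL,-1.0,0.0,-0.20
AR,1.0,0.0,-0.20
Cz,0.0,0.0,1.0
Pz,0.0,-0.60,0.85
Iz,0.0,-1.0,-0.05
FRONT,0.0,1.0,0.40
LEFT,-1.0,0.0,0.20
RIGHT,1.0,0.0,0.20
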