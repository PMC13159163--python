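system,gamma_low_uJ_per_m2,gamma_high_uJ_per_m2,Mw_kg_per_mol,class,phi
poly-rA,0.2,1.8,2500,condensate,
NPM1,5,30,165,condensate,
PGL-3,1,5,77,condensate,
Bik1,0.5,3,50,condensate,
urease,5,15,545,condensate,
Ddx4,1,8,80,condensate,
protamine,40,120,4.5,condensate,
poly-K,30,100,15,condensate,
tetrapeptide-FF,50,200,0.6,condensate,
tetrapeptide-WW,40,150,0.7,condensate,
tetrapeptide-YY,30,120,0.65,condensate,
tau,5,40,46,condensate,
FUS,1,10,75,condensate,
G3BP1,1,10,52,condensate,
MAP,50,200,10,condensate,
insulin crystal,2000,12000,5.8,solid,
lysozyme crystal,1000,5000,14.3,solid,
amyloid-beta40 fibril,5000,30000,4.3,solid,
apoferritin crystal,150,400,480,solid,
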