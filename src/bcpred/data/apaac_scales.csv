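# Hydrophobicity (Tanford-style, H1) and hydrophilicity (Hopp-Woods, H2)
# scales used by amphiphilic pseudo-amino-acid composition.
# Columns follow the canonical alphabetical one-letter order.
# version: 1
scale,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
hydrophobicity,0.62,0.29,-0.9,-0.74,1.19,0.48,-0.4,1.38,-1.5,1.06,0.64,-0.78,0.12,-0.85,-2.53,-0.18,-0.05,1.08,0.81,0.26
hydrophilicity,-0.5,-1.0,3.0,3.0,-2.5,0.0,-0.5,-1.8,3.0,-1.8,-1.3,0.2,0.0,0.2,3.0,0.3,-0.4,-1.5,-3.4,-2.3
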