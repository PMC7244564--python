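# Physicochemical property scales for normalized Moreau-Broto autocorrelation.
# Row names are AAindex accessions; the eight scales are the conventional
# autocorrelation defaults of Rcpi/protr-style descriptor engines:
# CIDH920105 normalized average hydrophobicity (Cid et al., 1992);
# BHAR880101 average flexibility index (Bhaskaran & Ponnuswamy, 1988);
# CHAM820101 polarizability parameter (Charton & Charton, 1982);
# CHAM820102 free energy of solution in water (Charton & Charton, 1982);
# CHOC760101 residue accessible surface area in tripeptide (Chothia, 1976);
# BIGC670101 residue volume (Bigelow, 1967);
# CHAM810101 steric parameter (Charton, 1981);
# DAYM780201 relative mutability (Dayhoff et al., 1978).
# Columns follow the canonical alphabetical one-letter order.
# version: 1
scale,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
CIDH920105,0.02,0.77,-1.04,-1.14,1.35,-0.8,0.26,1.81,-0.41,1.14,1.0,-0.77,-0.09,-1.1,-0.42,-0.97,-0.77,1.13,1.71,1.11
BHAR880101,0.357,0.346,0.511,0.497,0.314,0.544,0.323,0.462,0.466,0.365,0.295,0.463,0.509,0.493,0.529,0.507,0.444,0.386,0.305,0.42
CHAM820101,0.046,0.128,0.105,0.151,0.29,0.0,0.23,0.186,0.219,0.186,0.221,0.134,0.131,0.18,0.291,0.062,0.108,0.14,0.409,0.298
CHAM820102,-0.368,4.53,2.06,1.77,1.06,-0.525,0.0,0.791,0.0,1.07,0.656,0.0,-2.24,0.731,-1.03,-0.524,0.0,0.401,1.6,4.91
CHOC760101,115.0,135.0,150.0,190.0,210.0,75.0,195.0,175.0,200.0,170.0,185.0,160.0,145.0,180.0,225.0,115.0,140.0,155.0,255.0,230.0
BIGC670101,52.6,68.3,68.4,84.7,113.9,36.3,91.9,102.0,105.1,102.0,97.7,75.7,73.6,89.7,109.1,54.9,71.2,85.1,135.4,116.2
CHAM810101,0.52,0.62,0.76,0.68,0.7,0.0,0.7,1.02,0.68,0.98,0.78,0.76,0.36,0.68,0.68,0.53,0.5,0.76,0.7,0.7
DAYM780201,100.0,20.0,106.0,102.0,41.0,49.0,66.0,96.0,56.0,40.0,94.0,134.0,56.0,93.0,65.0,120.0,97.0,74.0,18.0,41.0
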