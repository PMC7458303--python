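antibody,pdb_code,cavity_volume,h3_hydrophobic_area,gly_count,label,source
Adalimumab,4nyl,0,340,1,immunogenic,crystal
Panitumumab,5sx4,0,176,1,immunogenic,crystal
Ustekinumab,3hmw,0,310,0,immunogenic,crystal
Avelumab,4nki,518,285,2,immunogenic,crystal
Durvalumab,5x8m,536,482,1,immunogenic,crystal
Necitumumab,6b3s,138,327,1,immunogenic,crystal
Nivolumab,5wt9,334,157,1,immunogenic,crystal
Ramucirumab,3s34,338,114,0,immunogenic,crystal
Guselkumab,4m6n,556,220,0,immunogenic,crystal
Certolizumab,5wuv,1224,310,1,immunogenic,crystal
Daclizumab,3nfs,0,112,1,immunogenic,crystal
Efalizumab,3eo9,0,319,0,immunogenic,crystal
Natalizumab,4irz,506,374,1,immunogenic,crystal
Atezolizumab,5x8l,684,263,2,immunogenic,crystal
Obinutuzumab,3pp4,576,304,2,immunogenic,crystal
Canakinumab,4g5z,342,244,1,non-immunogenic,crystal
Ofatumumab,3giz,1173,452,1,non-immunogenic,crystal
Ipilimumab,5tru,0,274,1,non-immunogenic,crystal
Belimumab,5y9j,1425,584,1,non-immunogenic,crystal
Bevacizumab,1bj1,1045,556,1,non-immunogenic,crystal
Eculizumab,5i5k,1077,549,2,non-immunogenic,crystal
Omalizumab,4x7s,942,357,1,non-immunogenic,crystal
Palivizumab,2hwz,825,318,0,non-immunogenic,crystal
Trastuzumab,6bhz,731,256,1,non-immunogenic,crystal
Alemtuzumab,1bey,0,228,1,non-immunogenic,crystal
Pembrolizumab,5ggs,2081,410,2,non-immunogenic,crystal
Ibalizumab,3o2d,1524,414,1,non-immunogenic,crystal
Pertuzumab,1s78,0,251,2,non-immunogenic,crystal
Bezlotoxumab,4np4,0,295,1,non-immunogenic,crystal
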