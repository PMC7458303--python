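antibody,h3_hydrophobic_area,gly_count,label,source,reported_prediction
Golimumab,589,1,immunogenic,modeled,0
Alirocumab,165,3,immunogenic,modeled,1
Dupilumab,653,3,immunogenic,modeled,0
Olaratumab,581,1,immunogenic,modeled,0
Sarilumab,123,1,immunogenic,modeled,1
Elotuzumab,239,0,immunogenic,modeled,1
Ixekizumab,354,1,immunogenic,modeled,1
Mepolizumab,289,2,immunogenic,modeled,1
Reslizumab,262,1,immunogenic,modeled,0
Vedolizumab,463,0,immunogenic,modeled,1
Inotuzumab,304,1,immunogenic,modeled,1
Benralizumab,482,1,immunogenic,modeled,0
Tildrakizumab,126,1,immunogenic,modeled,1
Denosumab,456,3,non-immunogenic,modeled,0
Daratumumab,715,4,non-immunogenic,modeled,0
Evolocumab,215,1,non-immunogenic,modeled,0
Raxibacumab,334,3,non-immunogenic,modeled,1
Secukinumab,874,1,non-immunogenic,modeled,1
Burosumab,219,1,non-immunogenic,modeled,0
Tocilizumab,422,1,non-immunogenic,modeled,0
Gemtuzumab,178,1,non-immunogenic,modeled,1
Idarucizumab,510,2,non-immunogenic,modeled,0
Ocrelizumab,399,2,non-immunogenic,modeled,0
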