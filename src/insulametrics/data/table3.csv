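Island,Topography,Isolation,Area,Population,Spp,Endemics
Corsica,480,0.691,8682,30,2680,284
Crete,394,0.952,8450,75,2214,392
Sardinia,261,0.963,24090,65,2438,195
Sicily,488,0.946,25711,186,3252,293
Cyprus,275,0.736,9251,120,1649,146
Malta (a),58,0.896,316,1715,1100,26
Balearic (a),133,0.880,4992,237,1551,145
Tuscan (a),171,0.522,313,110,1400,17
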