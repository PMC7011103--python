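no,lipid_class,species,precursor_detected,precursor_theoretical,ox_fa_fragment,fa_fragment,rt_min,precursor_mass_error_ppm
1,PC,PC(34:3)-O,830.555,830.557,293.212,255.232,6.96,1.81
2,PC,PC(34:4)-O,828.539,828.533,291.196,255.232,6.27,-7.12
3a,PC,PC(36:5)-O,854.555,854.551,293.212,279.232,6.57,-4.21
3b,PC,PC(36:5)-O,854.555,854.551,295.227,277.216,6.57,-4.21
4,PC,PC(36:6)-O,852.539,852.536,293.216,277.216,5.83,-3.40
5,PE,PE(34:2)-2O,746.497,746.490,293.216,255.232,7.06,-8.98
6,PE,PE(34:3)-2O,744.482,744.486,291.196,255.232,6.22,4.97
7,PE,PE(34:3)-O,728.487,728.483,293.212,255.232,7.16,-5.49
8,PE,PE(34:4)-O,726.471,726.474,291.196,255.232,6.52,4.13
9,PE,PE(36:4)-2O,770.497,770.500,293.212,279.232,6.51,3.50
10,PE,PE(36:4)-O,754.502,754.500,295.227,279.232,7.3,-3.31
11a,PE,PE(36:5)-2O,768.482,768.485,291.196,279.232,5.73,3.64
11b,PE,PE(36:5)-2O,768.482,768.485,293.216,277.216,5.73,3.64
12a,PE,PE(36:5)-O,752.487,752.488,293.212,279.232,6.62,1.59
12b,PE,PE(36:5)-O,752.487,752.488,295.227,277.216,6.62,1.59
13,PE,PE(36:6)-2O,766.466,766.466,291.196,277.216,4.75,0.00
14,PE,PE(36:6)-O,750.471,750.472,293.212,277.216,5.98,1.20
15,PG,PG(34:2)-O,761.496,761.499,295.227,255.232,6.37,3.81
16,PG,PG(34:3)-O,759.481,759.474,293.212,255.232,5.64,-9.35
17,PG,PG(34:4)-O,757.465,757.471,291.196,255.232,5.09,8.05
18,PI,PI(34:3)-O,847.497,847.492,293.212,255.232,5.34,-6.49
19,PI,PI(34:4)-O,845.482,845.479,295.227,255.232,4.76,-2.84
20,PI,PI(36:4)-O,873.513,873.515,295.227,279.232,5.59,2.29
21a,PI,PI(36:5)-O,871.487,871.487,293.212,279.232,4.96,0.01
21b,PI,PI(36:5)-O,871.487,871.487,295.227,277.216,4.96,0.01
22,PI,PI(36:6)-O,869.481,869.479,293.212,277.215,4.26,-1.96
23,PS,PS(34:3)-2O,701.439,701.440,291.196,255.232,5.04,1.71
24,PS,PS(34:3)-O,685.444,685.438,293.212,255.232,5.93,-8.75
25,PS,PS(34:4)-O,683.429,683.424,291.196,255.232,5.24,-7.48
26,PS,PS(34:4)-2O,699.424,699.421,291.196,255.232,4.21,-3.32
27,PS,PS(36:4)-2O,727.455,727.452,293.216,279.232,5.34,-4.81
28,PS,PS(36:4)-O,711.460,711.463,295.227,279.232,6.08,4.50
29a,PS,PS(36:5)-2O,725.439,725.435,291.196,279.232,4.45,-5.24
29b,PS,PS(36:5)-2O,725.439,725.435,293.216,277.216,4.45,-5.24
30a,PS,PS(36:5)-O,709.444,709.440,293.212,279.232,5.44,-6.06
30b,PS,PS(36:5)-O,709.444,709.440,295.227,277.216,5.44,-6.06
31,PS,PS(36:6)-O,707.429,707.423,293.212,277.216,4.81,-8.91
32,MGDG,MGDG(34:4)-O,825.536,825.528,291.196,255.232,7.29,-9.21
33a,MGDG,MGDG(36:5)-O,851.552,851.558,293.212,279.232,7.21,7.52
33b,MGDG,MGDG(36:5)-O,851.552,851.558,295.227,277.216,7.21,7.52
34,MGDG,MGDG(36:6)-O,849.536,849.535,293.212,277.216,6.47,-0.82
35,DGDG,DGDG(34:3)-O,989.605,989.607,293.212,277.216,6.82,2.02
36,DGDG,DGDG(36:4)-O,1015.620,1015.624,295.227,279.232,7.06,3.64
37a,DGDG,DGDG(36:5)-O,1013.605,1013.608,293.212,279.232,6.32,3.16
37b,DGDG,DGDG(36:5)-O,1013.605,1013.608,295.227,277.216,6.32,3.16
38,DGDG,DGDG(36:6)-O,1011.589,1011.591,293.212,277.216,5.54,2.17
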