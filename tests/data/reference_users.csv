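User ID,Weight,Height,PAL,BMI,BMR,Age,Iron Deficiency,T2D,Heart disease,Subgroup
1,68,1.73,1.195,22.72,1596.83,41,No,No,No,Healthy adults
2,66,1.76,1.495,21.31,1516.31,53,No,No,No,Healthy adults
3,83,1.82,1.495,25.06,1982.90,16,No,No,No,Healthy adolescents
4,51,1.71,1.495,17.44,1384.00,15,No,No,No,Healthy adolescents
5,61,1.67,1.495,21.87,1147.99,88,No,No,No,Healthy older adults
6,149,1.82,1.495,44.98,2503.77,80,No,No,No,Healthy older adults
7,91,1.82,1.495,27.47,1953.83,40,No,No,No,Adults who are overweight
8,97,1.85,1.195,28.34,2025.90,44,No,No,No,Adults who are overweight
9,48,1.77,2.2,15.32,1309.90,30,No,No,No,Athletes
10,46,1.63,1.745,17.31,1256.69,28,No,No,No,Athletes
11,130,1.64,1.195,48.33,1980.25,41,No,No,No,Adults who are obese
12,112,1.64,1.195,41.64,1809.47,42,No,No,No,Adults who are obese
13,138,1.75,1.195,45.06,2544.22,41,Yes,No,Yes,Adults with CVD
14,180,1.82,1.195,54.34,3106.42,47,No,No,Yes,Adults with CVD
15,124,1.69,1.195,43.41,1944.58,40,Yes,Yes,No,Adults with T2D
16,66,1.76,1.195,21.31,1607.14,37,No,Yes,No,Adults with T2D
17,95,1.74,1.495,31.38,1735.21,30,Yes,No,No,Adults with iron deficiency
18,72,1.61,1.195,27.78,1425.97,43,Yes,No,No,Adults with iron deficiency
19,85,1.76,1.495,27.44,1867.36,36,No,No,No,Adults with low fruit & veg
20,97,1.82,1.195,29.28,2034.21,40,No,No,No,Adults with low fruit & veg
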