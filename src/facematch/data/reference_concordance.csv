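k,rule,cohort,n,neither,both,software_only,clinician_only,mcnemar,p_value,kappa
1,two_of_three_definite,Williams,183,31,66,44,42,0.05,0.82925,0.02
1,two_of_three_definite,Rubinstein-Taybi,155,28,61,31,35,0.24,0.62246,0.11
1,two_of_three_definite,Floating Harbor,61,7,33,9,12,0.43,0.51269,0.16
1,two_of_three_definite,Coffin Lowry,154,42,41,47,24,7.45,0.00634,0.10
1,two_of_three_definite,Kabuki,195,23,88,18,66,27.43,<.00001,0.09
1,two_of_three_definite,Smith Magenis,124,34,38,34,18,4.92,0.02650,0.17
1,two_of_three_definite,PACS1,39,33,2,4,0,4.00,0.04550,0.46
1,two_of_three_definite,Kleefstra,128,52,9,63,4,51.96,<.00001,0.05
1,two_of_three_definite,Koolen-de Vries,120,30,37,29,24,0.47,0.49221,0.12
1,two_of_three_definite,Cornelia de Lange,441,52,264,65,60,0.20,0.65472,0.26
5,two_of_three_definite,Williams,183,2,103,73,5,59.28,<.00001,-0.02
5,two_of_three_definite,Rubinstein-Taybi,155,4,94,55,2,49.28,<.00001,0.06
5,two_of_three_definite,Floating Harbor,61,1,43,15,2,9.94,0.00162,0.02
5,two_of_three_definite,Coffin Lowry,154,15,59,74,6,57.80,<.00001,0.07
5,two_of_three_definite,Kabuki,195,2,148,39,6,24.20,<.00001,0.01
5,two_of_three_definite,Smith Magenis,124,2,56,66,0,66.00,<.00001,0.03
5,two_of_three_definite,PACS1,39,20,2,17,0,17.00,0.00004,0.11
5,two_of_three_definite,Kleefstra,128,18,11,97,2,91.16,<.00001,0.00
5,two_of_three_definite,Koolen-de Vries,120,17,54,42,7,25.00,<.00001,0.18
5,two_of_three_definite,Cornelia de Lange,441,10,311,107,13,73.63,<.00001,0.06
10,two_of_three_definite,Williams,183,1,105,74,3,65.47,<.00001,-0.02
10,two_of_three_definite,Rubinstein-Taybi,155,0,96,59,0,.,.,0.00
10,two_of_three_definite,Floating Harbor,61,1,43,15,2,9.94,0.00162,0.02
10,two_of_three_definite,Coffin Lowry,153,5,63,83,2,77.19,<.00001,0.02
10,two_of_three_definite,Kabuki,195,1,152,40,2,34.38,<.00001,0.02
10,two_of_three_definite,Smith Magenis,124,1,56,67,0,67.00,<.00001,0.01
10,two_of_three_definite,PACS1,39,11,2,26,0,26.00,<.00001,0.04
10,two_of_three_definite,Kleefstra,128,9,13,106,0,106.00,<.00001,0.02
10,two_of_three_definite,Koolen-de Vries,120,8,58,51,3,42.67,<.00001,0.09
10,two_of_three_definite,Cornelia de Lange,441,6,321,111,3,102.32,<.00001,0.06
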