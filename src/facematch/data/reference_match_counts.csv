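k,cohort,n_images,obs_match,obs_nomatch,exp_match,exp_nomatch,chi_square,p_value
1,Williams,183,110,73,11,172,938.43,<.00001
1,Rubinstein-Taybi,155,92,63,7,148,1068.28,<.00001
1,Floating Harbor,61,42,19,2,59,806.57,<.00001
1,Coffin Lowry,154,88,66,7,147,969.83,<.00001
1,Kabuki,195,106,89,12,183,776.29,<.00001
1,Smith Magenis,124,72,52,5,119,921.61,<.00001
1,PACS1,39,6,33,2,37,6.46,0.01106
1,Kleefstra,128,72,56,5,123,920.40,<.00001
1,Koolen-de Vries,120,66,54,4,116,978.17,<.00001
1,Cornelia de Lange,441,329,112,53,388,1627.70,<.00001
5,Williams,183,176,7,47,136,472.74,<.00001
5,Rubinstein-Taybi,155,149,6,34,121,493.94,<.00001
5,Floating Harbor,61,58,3,5,56,600.47,<.00001
5,Coffin Lowry,154,133,21,34,120,366.21,<.00001
5,Kabuki,195,187,8,53,142,461.78,<.00001
5,Smith Magenis,124,122,2,23,101,517.90,<.00001
5,PACS1,39,19,20,3,36,86.76,<.00001
5,Kleefstra,128,108,20,22,106,401.25,<.00001
5,Koolen-de Vries,120,96,24,20,100,342.02,<.00001
5,Cornelia de Lange,441,418,23,208,233,399.38,<.00001
10,Williams,183,179,4,82,101,205.76,<.00001
10,Rubinstein-Taybi,155,155,0,62,93,230.01,<.00001
10,Floating Harbor,61,58,3,11,50,239.81,<.00001
10,Coffin Lowry,154,146,8,61,93,193.83,<.00001
10,Kabuki,195,192,3,92,103,203.73,<.00001
10,Smith Magenis,124,123,1,41,83,242.03,<.00001
10,PACS1,39,28,11,4,35,153.84,<.00001
10,Kleefstra,128,119,9,40,88,224.08,<.00001
10,Koolen-de Vries,120,109,11,36,84,208.58,<.00001
10,Cornelia de Lange,441,432,9,317,124,147.09,<.00001
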