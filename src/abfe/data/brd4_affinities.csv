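ligand,dG_calc,dG_calc_sd,dG_exp,dG_exp_sd,docking_dG,table
1,-10.4,0.6,-9.8,0.1,,1
2,-9.5,0.4,-9.6,0.1,,1
3,-9.2,0.5,-9.0,0.1,,1
4,-9.4,0.8,-8.9,0.1,,1
5,-8.6,0.3,-8.8,0.1,,1
6,-9.9,0.8,-8.2,0.1,,1
7,-5.9,0.5,-7.8,0.1,,1
8,-7.8,0.3,-7.4,0.1,,1
9,-7.7,0.4,-7.3,0.0,,1
10,-5.9,0.2,-6.3,0.1,,1
11,-5.4,0.2,-5.6,,,1
1,-10.9,0.8,-9.8,0.1,-2.7,2
2,-10.1,0.4,-9.6,0.1,-4.7,2
3,-10.8,0.2,-9.0,0.1,-4.9,2
4,-9.0,0.8,-8.9,0.1,-3.4,2
5,-8.3,0.2,-8.8,0.1,-4.2,2
6,-10.6,0.3,-8.2,0.1,-4.6,2
7,-6.6,0.3,-7.8,0.1,-5.2,2
8,-10.2,0.2,-7.4,0.1,-4.2,2
9,-7.7,0.1,-7.3,0.0,-4.2,2
10,-6.2,0.1,-6.3,0.1,-3.2,2
11,-5.4,0.1,-5.6,,-4.8,2
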