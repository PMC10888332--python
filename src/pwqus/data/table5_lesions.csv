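id,birads,ac,sos,esd,esc,label
1,3,0.39,1508,86.67,2.4,benign
2,3,0.507,1542,103,1.293,benign
3,3,0.560,1492,77.53,2.392,benign
4,3,0.461,1530,64.94,2.847,benign
5,3,0.505,1557,96.12,2.118,benign
6,3,0.8061,1590,89.88,1.976,malignant
7,4,0.52,1538,94,4.153,benign
8,4,0.427,1507,94.12,3.247,benign
9,4,0.432,1525,55.6,1.58,malignant
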