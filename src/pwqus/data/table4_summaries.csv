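parameter,group,median,q1,q3
ac,benign,0.506,0.402,0.623
ac,malignant,0.666,0.609,0.731
sos,benign,1542,1525,1558.5
sos,malignant,1565,1550,1579
esd,benign,91.53,86.46,97.71
esd,malignant,83.76,74,90.6
esc,benign,2.396,1.926,3.008
esc,malignant,2.6,1.987,3.733
ac,idc,0.664,0.616,0.73
ac,dcis,0.682,0.577,0.877
sos,idc,1565,1552,1577
sos,dcis,1577,1525,1579
esd,idc,83.2,74,88.8
esd,dcis,97,90.33,101.9
esc,idc,2.684,2.22,3.804
esc,dcis,3.148,2.525,3.733
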