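# Per-tumor subregion summary: rabbit VX2 liver tumors after partial RFA
# units: ktrans 1/min; ve fraction; vp fraction; mvd vessels/field
tumor_id,region,ktrans,ve,vp,mvd
1,CNA,0.00,0.33,0.00,0.00
1,PNA,0.03,0.03,0.01,4.60
1,VTA,0.03,0.04,0.02,15.40
2,CNA,0.04,0.04,0.03,1.80
2,PNA,0.11,0.07,0.03,6.40
2,VTA,0.48,0.08,0.02,17.20
3,CNA,0.01,0.17,0.01,0.00
3,PNA,0.02,0.05,0.02,3.40
3,VTA,0.03,0.05,0.03,16.60
4,CNA,0.00,0.20,0.01,0.40
4,PNA,0.09,0.04,0.01,6.60
4,VTA,0.45,0.08,0.02,16.40
5,CNA,0.05,0.07,0.08,0.60
5,PNA,0.34,0.16,0.08,5.25
5,VTA,1.13,0.22,0.09,14.40
6,CNA,0.03,0.24,0.03,1.00
6,PNA,0.16,0.25,0.02,7.60
6,VTA,1.00,0.17,0.08,12.40
7,CNA,0.02,0.05,0.01,0.20
7,PNA,0.23,0.29,0.13,5.60
7,VTA,0.60,0.26,0.03,16.80
8,CNA,0.02,0.66,0.00,0.40
8,PNA,0.16,0.16,0.02,5.00
8,VTA,0.71,0.17,0.02,14.67
9,CNA,0.28,0.14,0.01,1.00
9,PNA,1.50,0.19,0.02,14.60
9,VTA,2.47,0.19,0.03,31.40
10,CNA,0.07,0.22,0.00,0.60
10,PNA,0.17,0.21,0.06,7.00
10,VTA,1.17,0.23,0.06,26.00
11,CNA,0.02,0.56,0.01,3.40
11,PNA,0.23,0.13,0.04,4.40
11,VTA,1.07,0.24,0.06,8.20
12,CNA,0.05,0.10,0.01,1.40
12,PNA,0.16,0.08,0.02,4.25
12,VTA,0.42,0.08,0.02,11.00
13,CNA,0.04,0.04,0.02,1.20
13,PNA,0.91,0.21,0.00,21.00
13,VTA,4.03,0.13,0.00,23.40
14,CNA,0.01,0.59,0.00,0.20
14,PNA,0.16,0.08,0.03,5.00
14,VTA,0.85,0.11,0.01,18.40
15,CNA,0.02,0.05,0.01,4.50
15,PNA,0.13,0.06,0.02,5.00
15,VTA,0.56,0.07,0.00,11.00
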