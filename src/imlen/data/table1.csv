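patient,anomaly,ostium_location,radiologic,computational,surgical,repair
1,L-AAOCA,"1c, IV",0,4.2,6,U
2,L-AAOCA,"1c, III/IV",3–4,4.9,1–2,U
3,L-AAOCA,"2c, II",2.8,8.3,0,R
4,L-AAOCA,Unknown,10,6.4,7,U
5,L-AAOCA,"1c, II",3,8.6,8,R
6,L-AAOCA,"1c, II",8.9,4.3,9,U
7,L-AAOCA,"1b, II",0 (or “Short”),8.6,10,U
8,L-AAOCA,"1c, II",0,3.7,4,U
9,L-AAOCA,"1c, II/III",10,13.9,11,U
10,R-AAOCA,"2a, II/III",6–7,3.9,5–6,U
11,R-AAOCA,"2a, III",2.5,3.3,3,U
12,R-AAOCA,"2a, III",8.2,3.7,7,U
13,R-AAOCA,"2a, II",4.8–5,9.4,4.5,U
14,R-AAOCA,"2a, I",8.5–9,2.9,6,U
15,R-AAOCA,"2a, II",6.8,7.9,6,U
16,R-AAOCA,"2a, II",4–4.4,9,4,U
17,R-AAOCA,"2a, III",7.4,8.5,7,U
18,R-AAOCA,"2a, II",12,4.2,4,U
19,R-AAOCA,"2a, II",8.8–10.8,11.2,4,U
20,R-AAOCA,"2a, III",12,9.6,9,U
21,R-AAOCA,"2a, III",4,6.4,4,R
22,R-AAOCA,"2a, III",6,5.9,6,U
23,R-AAOCA,"2a, III",6,7.2,6,R
24,R-AAOCA,"2a, II",2.4,7.5,3,U
25,R-AAOCA,"2a, II",9–9.5,3.8,9,U
26,R-AAOCA,"2a, II/III",8.5,1.5,0 (or “Short”),R
27,R-AAOCA,Unknown,3.5,9.3,7,U
28,R-AAOCA,"2a, II",5.8,10,6,U
29,R-AAOCA,"Unknown, III",6,4.3,5,U
30,R-AAOCA,"2b, IV",6.5–7,8.1,6.5,U
31,R-AAOCA,"2a, IV",5–6,6.9,5,U
32,R-AAOCA,"2a, II",3,1.5,5,U
33,R-AAOCA,"2a, I",6,11.4,8,R
34,R-AAOCA,"2a, II",8,11.1,7,U
35,R-AAOCA,"2a, III",7,4.3,9,U
36,R-AAOCA,"2a, III",7,5.7,6,U
37,R-AAOCA,"2a, II",11–12,6.8,8,U
38,R-AAOCA,"2a, III",9,6.3,5,U
39,R-AAOCA,"2a, II",7.4,6,6,U
40,R-AAOCA,"2a, III",6,6.6,6,U
41,R-AAOCA,"2c, IV",4,0.4,4,U
42,R-AAOCA,"2a, III",3–4,8.4,3,U
43,R-AAOCA,"Unknown, IV",4.4,5.3,5,U
44,R-AAOCA,"2a, II",7,7.1,3,U
45,R-AAOCA,"2a, II",8,10,7,U
46,R-AAOCA,"2a, II",9.5,6.5,7,U
47,R-AAOCA,"2a, II",9–9.4,1.3,8,U
48,R-AAOCA,"2a, II",6.5,6.8,6,U
49,R-AAOCA,"2a, II",5.8,9.9,5,R
50,R-AAOCA,"2a, II",4,6.2,4,R
51,R-AAOCA,"2a, II",8,4,5,U
52,R-AAOCA,"2a, II",8.5–10,4.2,7,U
53,R-AAOCA,"2a, II",7.6,2.9,7,R
54,R-AAOCA,"2a, III",6–7,23.1,16,R
55,R-AAOCA,"2a, I",6,10.1,6,R
56,R-AAOCA,"2a, II",7,12,8,U
57,R-AAOCA,"2a, II",9,9.6,9,U
58,R-AAOCA/LAD MB,Unknown,7,4,10,U
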