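row,plate,well,name,vcanb_score,mbp_score,fr24_score
1,S18,C09,CARAPIN-8(9)-ENE,0.00,8.50,9.00
2,S25,D08,3-ISOBUTYL-1-METHYLXANTHINE (IBMX),2.00,8.50,9.00
3,S17,F05,DEOXYGEDUNIN,2.00,8.00,9.00
4,S23,F10,DIHYDROFISSINOLIDE,2.67,7.50,9.00
5,S04,B02,IVERMECTIN,2.33,7.00,9.00
6,T01,F06,SC-10,5.67,6.50,9.00
7,T01,H11,"1,3-Dipropyl-8-phenylxanthine",3.33,6.50,9.00
8,S17,E02,3-DEOXO-3beta-ACETOXYDEOXYDIHYDROGEDUNIN,0.00,6.50,9.00
9,T11,F07,Cilnidipine,2.00,6.50,9.00
10,S13,F03,AMIODARONE HYDROCHLORIDE,5.00,6.50,9.00
11,S06,E02,HYDROCORTISONE HEMISUCCINATE,3.67,6.00,9.00
12,T01,C04,(RS)-(Tetrazol-5-yl)glycine,3.00,5.00,9.00
13,S02,E05,LOMEFLOXACIN HYDROCHLORIDE,5.33,5.00,9.00
14,S13,E04,ETHAMIVAN,4.67,5.00,9.00
15,T08,B04,CGS 15943,5.33,4.50,9.00
16,S13,E09,ASTEMIZOLE,4.67,4.50,9.00
17,T02,A09,SKF 91488 dihydrochloride,3.00,4.00,9.00
18,S25,F05,11alpha-HYDROXYPROGESTERONE HEMISUCCINATE,2.67,4.00,9.00
19,T14,A07,Efonidipine hydrochloride monoethanolate,3.67,4.00,9.00
20,T05,C09,Nifedipine,4.33,7.00,8.00
21,T05,E08,CGP 37157,3.67,6.50,8.00
22,S05,D03,DANAZOL,1.00,5.00,8.00
23,S18,H09,XANTHYLETIN,1.00,4.50,8.00
24,S18,A06,FERULIC ACID,3.67,4.00,8.00
25,S18,F02,alpha-DIHYDROGEDUNOL,2.33,4.00,8.00
26,T05,F04,(S)-(+)-Niguldipine hydrochloride,3.67,5.00,7.00
27,T07,F02,Tracazolate hydrochloride,2.33,4.50,7.00
28,S10,E02,NIMODIPINE,0.33,7.00,6.00
29,S17,E06,3beta-ACETOXYDEOXODIHYDROGEDUNIN,2.00,4.50,5.00
30,S17,F02,DIHYDROGEDUNIN,1.67,5.00,2.00
31,S22,F09,TANGERITIN,1.33,5.50,1.00
32,S10,F07,COLFORSIN,0.00,9.00,0.00
33,T04,G02,Imiloxan hydrochloride,0.67,9.00,ND
34,S24,C03,3alpha-ACETOXYDIHYDRODEOXYGEDUNIN,0.33,8.50,DE
35,S11,E02,EZETIMIBE,2.00,7.50,0.00
36,S10,E06,NITRENDIPINE,1.33,7.00,ND
37,S11,E08,ROSUVASTATIN CALCIUM,0.00,6.00,0.00
38,S22,C07,DEMETHYLNOBILETIN,0.00,6.00,0.00
39,S22,G11,HEXAMETHYLQUERCETAGETIN,0.00,5.50,DE
40,S22,F08,NOBILETIN,0.00,5.00,DE
41,S12,H07,PREGNENOLONE SUCCINATE,4.67,4.00,DE
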