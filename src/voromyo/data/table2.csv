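case,vessel,grade,lv_mass_g,subtended_mass_g,defect_mass_g,defect_lesion_mass_g,percent
1,mLAD,70,98,22,11,10,100
1,dRCA,50,98,29,11,1,100
2,mLAD,70,118,15,3,2,100
2,D1,70,118,20,3,0,100
2,dRCA,50,118,49,3,1,100
3,LM,50,162,94,12,8,100
3,dRCA,50,162,63,12,4,100
4,pLAD,50,127,46,6,0,100
4,Cx,50,127,57,6,6,100
5,pLAD,50,136,42,9,5,100
5,dRCA,50,136,21,9,2,100
5,AL,50,136,30,9,2,100
6,pLAD,50,220,105,13,13,100
7,mLAD,50,115,63,5,5,100
8,pLAD,50,73,38,6,6,100
8,Cx,50,73,17,6,0,100
9,LM,50,67,46,5,5,100
10,pLAD,50,90,42,5,5,100
11,pLAD,50,90,33,10,2,100
11,pRCA,50,90,29,10,8,100
11,Cx,50,90,27,10,0,100
12,mLAD,50,87,35,10,10,100
13,mLAD,70,255,111,8,8,100
13,Cx,50,255,25,8,0,100
14,dLAD,50,98,7,2,0,100
14,D1,70,98,30,2,1,100
14,MO,50,98,18,2,0,100
14,AL,50,98,10,2,1,100
15,pLAD,50,64,45,3,1,100
15,mRCA,50,64,13,3,2,100
15,Cx,50,64,9,3,0,100
16,pLAD,50,101,40,4,2,100
16,pRCA,50,101,28,4,2,100
16,Cx,50,101,28,4,0,100
17,pLAD,50,102,46,3,2,100
17,IM,70,102,34,3,1,100
18,pLAD,50,89,62,7,4,100
18,pRCA,50,89,24,7,3,100
19,pLAD,50,104,39,7,4,100
19,dRCA,50,104,21,7,3,100
19,Cx,50,104,24,7,0,100
20,pLAD,50,106,48,11,10,91
20,Cx,50,106,35,11,0,91
21,pLAD,50,134,45,8,7,88
22,pLAD,50,94,28,7,6,86
22,pRCA,70,94,0,7,0,86
22,Cx,50,94,51,7,0,86
23,mLAD,50,124,36,7,6,86
23,pRCA,50,124,14,7,0,86
23,Cx,50,124,31,7,0,86
24,pLAD,70,100,38,12,9,83
24,mRCA,70,100,0,12,0,83
24,MO,50,100,25,12,1,83
25,pLAD,50,132,64,8,6,75
26,mLAD,50,139,37,7,5,71
27,pLAD,70,96,43,5,3,60
28,mRCA,50,145,51,5,3,60
29,mLAD,50,110,39,9,5,56
30,dLAD,50,163,43,4,1,50
30,D2,50,163,25,4,1,50
31,dLAD,70,130,22,3,1,33
32,mLAD,50,133,47,4,1,25
32,pRCA,50,133,0,4,0,25
33,pLAD,50,77,30,5,1,20
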