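index,name,region,laterality,group_id
1,Bregma,cranial,midline,cranial
2,CFM,cranial,midline,cranial
3,Na,cranial,midline,cranial
4,ANS,cranial,midline,cranial
5,Or(L),cranial,L,cranial
6,Or(R),cranial,R,cranial
7,Po(L),cranial,L,cranial
8,Po(R),cranial,R,cranial
9,MxDML,cranial,midline,midsag
10,Od,cranial,midline,midsag
11,PNS,cranial,midline,midsag
12,Sella,cranial,midline,cranial
13,Basion,cranial,midline,cranial
14,Opisthion,cranial,midline,cranial
15,Glabella,cranial,midline,cranial
16,Rhinion,cranial,midline,cranial
17,A-point,cranial,midline,cranial
18,Prosthion,cranial,midline,cranial
19,SC,cranial,midline,cranial
20,Staphylion,cranial,midline,cranial
21,Lambda,cranial,midline,cranial
22,Opisthocranion,cranial,midline,cranial
23,Inion,cranial,midline,cranial
24,Vomer,cranial,midline,cranial
25,Zygion(L),cranial,L,cranial
26,Zygion(R),cranial,R,cranial
27,FZ(L),cranial,L,cranial
28,FZ(R),cranial,R,cranial
29,Jugale(L),cranial,L,cranial
30,Jugale(R),cranial,R,cranial
31,IOF(L),cranial,L,cranial
32,IOF(R),cranial,R,cranial
33,Ek(L),cranial,L,cranial
34,Ek(R),cranial,R,cranial
35,KeyRidge(L),cranial,L,cranial
36,KeyRidge(R),cranial,R,cranial
37,Mastoidale(L),cranial,L,cranial
38,Mastoidale(R),cranial,R,cranial
39,Pterygoid(L),cranial,L,cranial
40,Pterygoid(R),cranial,R,cranial
41,Euryon(L),cranial,L,cranial
42,Euryon(R),cranial,R,cranial
43,U1Tip(L),cranial,L,cranial
44,U1Tip(R),cranial,R,cranial
45,U6MB(L),cranial,L,cranial
46,U6MB(R),cranial,R,cranial
47,MF(L),mandibular,L,body_L
48,MF(R),mandibular,R,body_R
49,COR(L),mandibular,L,condyle_L
50,MCP(L),mandibular,L,condyle_L
51,LCP(L),mandibular,L,condyle_L
52,Cp(L),mandibular,L,condyle_L
53,Ct-in(L),mandibular,L,condyle_L
54,Ct-out(L),mandibular,L,condyle_L
55,COR(R),mandibular,R,condyle_R
56,MCP(R),mandibular,R,condyle_R
57,LCP(R),mandibular,R,condyle_R
58,Cp(R),mandibular,R,condyle_R
59,Ct-in(R),mandibular,R,condyle_R
60,Ct-out(R),mandibular,R,condyle_R
61,Menton,mandibular,midline,symphysis
62,Pogonion,mandibular,midline,symphysis
63,B-point,mandibular,midline,symphysis
64,Gnathion,mandibular,midline,symphysis
65,Infradentale,mandibular,midline,symphysis
66,IDML,mandibular,midline,symphysis
67,Go(L),mandibular,L,ramus_L
68,Sigmoid(L),mandibular,L,ramus_L
69,MandF(L),mandibular,L,ramus_L
70,Ag(L),mandibular,L,ramus_L
71,RamusPost(L),mandibular,L,ramus_L
72,Go(R),mandibular,R,ramus_R
73,Sigmoid(R),mandibular,R,ramus_R
74,MandF(R),mandibular,R,ramus_R
75,Ag(R),mandibular,R,ramus_R
76,RamusPost(R),mandibular,R,ramus_R
77,L6MB(L),mandibular,L,body_L
78,MT(L),mandibular,L,symphysis
79,BodyInf(L),mandibular,L,body_L
80,L6MB(R),mandibular,R,body_R
81,MT(R),mandibular,R,symphysis
82,BodyInf(R),mandibular,R,body_R
83,L1Tip(L),mandibular,L,arch_L
84,L3Tip(L),mandibular,L,arch_L
85,ArchMid(L),mandibular,L,arch_L
86,AlvCrest(L),mandibular,L,arch_L
87,L1Tip(R),mandibular,R,arch_R
88,L3Tip(R),mandibular,R,arch_R
89,ArchMid(R),mandibular,R,arch_R
90,AlvCrest(R),mandibular,R,arch_R
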