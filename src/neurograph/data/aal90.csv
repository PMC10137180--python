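index,abbrev,name,hemisphere,lobe
1,PreCG.L,Precentral gyrus,L,frontal
2,PreCG.R,Precentral gyrus,R,frontal
3,SFGdor.L,"Superior frontal gyrus, dorsolateral",L,frontal
4,SFGdor.R,"Superior frontal gyrus, dorsolateral",R,frontal
5,ORBsup.L,"Superior frontal gyrus, orbital part",L,frontal
6,ORBsup.R,"Superior frontal gyrus, orbital part",R,frontal
7,MFG.L,Middle frontal gyrus,L,frontal
8,MFG.R,Middle frontal gyrus,R,frontal
9,ORBmid.L,"Middle frontal gyrus, orbital part",L,frontal
10,ORBmid.R,"Middle frontal gyrus, orbital part",R,frontal
11,IFGoperc.L,"Inferior frontal gyrus, opercular part",L,frontal
12,IFGoperc.R,"Inferior frontal gyrus, opercular part",R,frontal
13,IFGtriang.L,"Inferior frontal gyrus, triangular part",L,frontal
14,IFGtriang.R,"Inferior frontal gyrus, triangular part",R,frontal
15,ORBinf.L,"Inferior frontal gyrus, orbital part",L,frontal
16,ORBinf.R,"Inferior frontal gyrus, orbital part",R,frontal
17,ROL.L,Rolandic operculum,L,frontal
18,ROL.R,Rolandic operculum,R,frontal
19,SMA.L,Supplementary motor area,L,frontal
20,SMA.R,Supplementary motor area,R,frontal
21,OLF.L,Olfactory cortex,L,frontal
22,OLF.R,Olfactory cortex,R,frontal
23,SFGmed.L,"Superior frontal gyrus, medial",L,frontal
24,SFGmed.R,"Superior frontal gyrus, medial",R,frontal
25,ORBsupmed.L,"Superior frontal gyrus, medial orbital",L,frontal
26,ORBsupmed.R,"Superior frontal gyrus, medial orbital",R,frontal
27,REC.L,Gyrus rectus,L,frontal
28,REC.R,Gyrus rectus,R,frontal
29,INS.L,Insula,L,insula
30,INS.R,Insula,R,insula
31,ACG.L,Anterior cingulate and paracingulate gyri,L,limbic
32,ACG.R,Anterior cingulate and paracingulate gyri,R,limbic
33,MCG.L,Median cingulate and paracingulate gyri,L,limbic
34,MCG.R,Median cingulate and paracingulate gyri,R,limbic
35,PCG.L,Posterior cingulate gyrus,L,limbic
36,PCG.R,Posterior cingulate gyrus,R,limbic
37,HIP.L,Hippocampus,L,limbic
38,HIP.R,Hippocampus,R,limbic
39,PHG.L,Parahippocampal gyrus,L,limbic
40,PHG.R,Parahippocampal gyrus,R,limbic
41,AMYG.L,Amygdala,L,limbic
42,AMYG.R,Amygdala,R,limbic
43,CAL.L,Calcarine fissure and surrounding cortex,L,occipital
44,CAL.R,Calcarine fissure and surrounding cortex,R,occipital
45,CUN.L,Cuneus,L,occipital
46,CUN.R,Cuneus,R,occipital
47,LING.L,Lingual gyrus,L,occipital
48,LING.R,Lingual gyrus,R,occipital
49,SOG.L,Superior occipital gyrus,L,occipital
50,SOG.R,Superior occipital gyrus,R,occipital
51,MOG.L,Middle occipital gyrus,L,occipital
52,MOG.R,Middle occipital gyrus,R,occipital
53,IOG.L,Inferior occipital gyrus,L,occipital
54,IOG.R,Inferior occipital gyrus,R,occipital
55,FFG.L,Fusiform gyrus,L,temporal
56,FFG.R,Fusiform gyrus,R,temporal
57,PoCG.L,Postcentral gyrus,L,parietal
58,PoCG.R,Postcentral gyrus,R,parietal
59,SPG.L,Superior parietal gyrus,L,parietal
60,SPG.R,Superior parietal gyrus,R,parietal
61,IPL.L,"Inferior parietal, but supramarginal and angular gyri",L,parietal
62,IPL.R,"Inferior parietal, but supramarginal and angular gyri",R,parietal
63,SMG.L,Supramarginal gyrus,L,parietal
64,SMG.R,Supramarginal gyrus,R,parietal
65,ANG.L,Angular gyrus,L,parietal
66,ANG.R,Angular gyrus,R,parietal
67,PCUN.L,Precuneus,L,parietal
68,PCUN.R,Precuneus,R,parietal
69,PCL.L,Paracentral lobule,L,frontal
70,PCL.R,Paracentral lobule,R,frontal
71,CAU.L,Caudate nucleus,L,subcortex
72,CAU.R,Caudate nucleus,R,subcortex
73,PUT.L,"Lenticular nucleus, putamen",L,subcortex
74,PUT.R,"Lenticular nucleus, putamen",R,subcortex
75,PAL.L,"Lenticular nucleus, pallidum",L,subcortex
76,PAL.R,"Lenticular nucleus, pallidum",R,subcortex
77,THA.L,Thalamus,L,subcortex
78,THA.R,Thalamus,R,subcortex
79,HES.L,Heschl gyrus,L,temporal
80,HES.R,Heschl gyrus,R,temporal
81,STG.L,Superior temporal gyrus,L,temporal
82,STG.R,Superior temporal gyrus,R,temporal
83,TPOsup.L,Temporal pole: superior temporal gyrus,L,temporal
84,TPOsup.R,Temporal pole: superior temporal gyrus,R,temporal
85,MTG.L,Middle temporal gyrus,L,temporal
86,MTG.R,Middle temporal gyrus,R,temporal
87,TPOmid.L,Temporal pole: middle temporal gyrus,L,temporal
88,TPOmid.R,Temporal pole: middle temporal gyrus,R,temporal
89,ITG.L,Inferior temporal gyrus,L,temporal
90,ITG.R,Inferior temporal gyrus,R,temporal
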