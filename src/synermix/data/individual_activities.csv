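compound,assay,concentration_um,mean,sd
P,FRAP,100,282,5
P,FRAP,500,1014,14
P,FRAP,1000,2341,32
P,ORAC,2.5,30,0.9
P,ORAC,5,57,2
Ge,FRAP,100,294,4
Ge,FRAP,500,1710,81
Ge,FRAP,1000,3186,104
Ge,ORAC,2.5,29,1
Ge,ORAC,5,53,0
G,FRAP,100,494,3
G,FRAP,500,2478,17
G,FRAP,1000,5033,106
G,ORAC,2.5,23,1
G,ORAC,5,28,1
V,FRAP,100,193,2
V,FRAP,500,542,4
V,FRAP,1000,850,13
V,ORAC,2.5,26,1
V,ORAC,5,56,1
Sy,FRAP,100,245,5
Sy,FRAP,500,1514,19
Sy,FRAP,1000,3207,111
Sy,ORAC,2.5,29,2
Sy,ORAC,5,40,1
pC,FRAP,100,23.9,2
pC,FRAP,500,61.8,1
pC,FRAP,1000,113,3
pC,ORAC,2.5,20,2
pC,ORAC,5,33,1
C,FRAP,100,476,17
C,FRAP,500,1321,2
C,FRAP,1000,2125,18
C,ORAC,2.5,31,2
C,ORAC,5,60,1
F,FRAP,100,260,6
F,FRAP,500,885,2
F,FRAP,1000,1706,38
F,ORAC,2.5,26,2
F,ORAC,5,45,0
Si,FRAP,100,235,8
Si,FRAP,500,1201,0
Si,FRAP,1000,2186,24
Si,ORAC,2.5,25,1
Si,ORAC,5,44,1
R,FRAP,100,413,14
R,FRAP,500,1803,50
R,FRAP,1000,3656,148
R,ORAC,2.5,50,2
R,ORAC,5,92,2
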