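table,mixture,assay,concentration_um,experimental_mean,experimental_sd,printed_theoretical,printed_difference
3,P+Ge,FRAP,100,520,2,288,81
3,P+Ge,FRAP,500,1320,15,1362,-3.1
3,P+Ge,FRAP,1000,2832,22,2763,2.5
3,P+G,FRAP,100,349,7,388,-10
3,P+G,FRAP,500,2181,16,1746,25
3,P+G,FRAP,1000,3623,7,3687,-1.7
3,P+V,FRAP,100,101,3,237,-58
3,P+V,FRAP,500,559,3,778,-28
3,P+V,FRAP,1000,1414,8,1595,-11
3,P+Sy,FRAP,100,274,5,263,4.0
3,P+Sy,FRAP,500,1280,19,1264,1.3
3,P+Sy,FRAP,1000,2705,10,2774,-2.5
3,Ge+G,FRAP,100,542,5,394,38
3,Ge+G,FRAP,500,2034,19,2094,-2.9
3,Ge+G,FRAP,1000,3937,9,4109,-4.2
3,Ge+V,FRAP,100,311,3,243,28
3,Ge+V,FRAP,500,825,10,1126,-27
3,Ge+V,FRAP,1000,1440,23,2018,-29
3,Ge+Sy,FRAP,100,410,3,270,52
3,Ge+Sy,FRAP,500,2539,4,1612,58
3,Ge+Sy,FRAP,1000,2974,3,3197,-7.0
3,G+V,FRAP,100,229,5,343,-33
3,G+V,FRAP,500,1237,23,1510,-18
3,G+V,FRAP,1000,2861,15,2942,-2.8
3,G+Sy,FRAP,100,275,2,370,-26
3,G+Sy,FRAP,500,1814,36,1996,-9.1
3,G+Sy,FRAP,1000,3599,12,4120,-13
3,V+Sy,FRAP,100,179,0,219,-19
3,V+Sy,FRAP,500,910,5,1028,-12
3,V+Sy,FRAP,1000,1440,23,2029,-29
3,P+Ge+G,FRAP,100,166,1,356,-54
3,P+Ge+G,FRAP,500,2199,28,1734,27
3,P+Ge+G,FRAP,1000,3811,6,3520,8.3
3,P+Ge+V,FRAP,100,317,3,256,24
3,P+Ge+V,FRAP,500,1338,3,1089,23
3,P+Ge+V,FRAP,1000,1871,5,2126,-12
3,P+Ge+Sy,FRAP,100,749,1,274,174
3,P+Ge+Sy,FRAP,500,1509,13,1413,6.8
3,P+Ge+Sy,FRAP,1000,2881,6,2911,-1.1
3,P+G+V,FRAP,100,248,1,323,-23
3,P+G+V,FRAP,500,1468,15,1345,9.2
3,P+G+V,FRAP,1000,2591,8,2741,-5.5
3,P+G+Sy,FRAP,100,349,6,340,2.6
3,P+G+Sy,FRAP,500,1616,8,1668,-3.2
3,P+G+Sy,FRAP,1000,2741,50,3527,-22
3,P+V+Sy,FRAP,100,210,2,240,-13
3,P+V+Sy,FRAP,500,947,3,1023,-7.5
3,P+V+Sy,FRAP,1000,1786,41,2133,-16
3,Ge+G+V,FRAP,100,409,3,327,25
3,Ge+G+V,FRAP,500,1611.3,8,1577,2.2
3,Ge+G+V,FRAP,1000,2430,8,3023,-20
3,Ge+G+Sy,FRAP,100,519,3,344,51
3,Ge+G+Sy,FRAP,500,1822.4,12,1901,-4.1
3,Ge+G+Sy,FRAP,1000,3294,47,3809,-14
3,G+V+Sy,FRAP,100,245,4,311,-21
3,G+V+Sy,FRAP,500,1176.8,6,1511,-22
3,G+V+Sy,FRAP,1000,2265,21,3030,-25
3,V+Sy+Ge,FRAP,100,335,4,244,37
3,V+Sy+Ge,FRAP,500,1023.5,6,1255,-19
3,V+Sy+Ge,FRAP,1000,2014,7,2414,-17
3,P+Ge+G+V,FRAP,100,414,3,316,31
3,P+Ge+G+V,FRAP,500,1390,2,1436,-3.2
3,P+Ge+G+V,FRAP,1000,2695,20,2852,-5.5
3,P+Ge+V+Sy,FRAP,100,367,1,253,45
3,P+Ge+V+Sy,FRAP,500,956,4,1195,-20
3,P+Ge+V+Sy,FRAP,1000,1958,4,2396,-18
3,Ge+G+V+Sy,FRAP,100,412,5,307,34
3,Ge+G+V+Sy,FRAP,500,1236,2,1561,-21
3,Ge+G+V+Sy,FRAP,1000,2470,27,3069,-20
3,G+V+Sy+P,FRAP,100,236,0,303,-21
3,G+V+Sy+P,FRAP,500,1291,31,1387,-6.9
3,G+V+Sy+P,FRAP,1000,2789,46,2858,-2.4
3,Sy+P+Ge+G,FRAP,100,512,5,329,57
3,Sy+P+Ge+G,FRAP,500,1594,15,1679,-5.1
3,Sy+P+Ge+G,FRAP,1000,3207,43,3442,-6.8
3,P+Ge+G+V+Sy,FRAP,100,439,1,302,46
3,P+Ge+G+V+Sy,FRAP,500,1257,10,1452,-13
3,P+Ge+G+V+Sy,FRAP,1000,2876,5,2923,-1.6
4,pC+C,FRAP,100,161,10,250,-36
4,pC+C,FRAP,500,779,18,691,13
4,pC+C,FRAP,1000,1479,42,1119,32
4,pC+F,FRAP,100,95,2,142,-33
4,pC+F,FRAP,500,537,31,4474,-88
4,pC+F,FRAP,1000,1046,9,909,15
4,pC+Si,FRAP,100,223,10,130,72
4,pC+Si,FRAP,500,655,32,631,3.8
4,pC+Si,FRAP,1000,1321,39,1150,15
4,pC+R,FRAP,100,197,10,219,-10
4,pC+R,FRAP,500,1357,26,932,46
4,pC+R,FRAP,1000,2635,404,1885,40
4,C+F,FRAP,100,314,2,368,-15
4,C+F,FRAP,500,1227,28,5103,-76
4,C+F,FRAP,1000,2049,28,1915,7.0
4,C+Si,FRAP,100,342,20,3560,-4.0
4,C+Si,FRAP,500,1362,14,1261,8.0
4,C+Si,FRAP,1000,2542,87,2155,18
4,C+R,FRAP,100,428,44,445,-3.8
4,C+R,FRAP,500,1751,155,1562,12
4,C+R,FRAP,1000,3347,122,2890,16
4,F+Si,FRAP,100,501,5,248,102
4,F+Si,FRAP,500,1234,25,5043,-76
4,F+Si,FRAP,1000,2303,62,1946,18
4,F+R,FRAP,100,322,7,336,-4.2
4,F+R,FRAP,500,1467,19,5344,-73
4,F+R,FRAP,1000,2812,57,2681,4.9
4,Si+R,FRAP,100,307,3,324,-5.2
4,Si+R,FRAP,500,1674,56,1502,11
4,Si+R,FRAP,1000,3394,55,2921,16
4,pC+C+F,FRAP,100,181,2,253,-28
4,pC+C+F,FRAP,500,716,18,3423,-79
4,pC+C+F,FRAP,1000,1472,26,1315,12
4,pC+C+Si,FRAP,100,190,9,245,-23
4,pC+C+Si,FRAP,500,849,19,861,-1.4
4,pC+C+Si,FRAP,1000,1559,21,1475,5.7
4,pC+C+R,FRAP,100,691,39,305,127
4,pC+C+R,FRAP,500,1567,32,1062,48
4,pC+C+R,FRAP,1000,2178,19,1965,11
4,pC+F+Si,FRAP,100,171,3,173,-0.9
4,pC+F+Si,FRAP,500,737,60,3383,-78
4,pC+F+Si,FRAP,1000,1436,58,1335,7.6
4,pC+F+R,FRAP,100,63,7,232,-73
4,pC+F+R,FRAP,500,954,8,3584,-73
4,pC+F+R,FRAP,1000,1780,54,1825,-2.5
4,pC+Si+R,FRAP,100,216,6,224,-3.6
4,pC+Si+R,FRAP,500,947,6,1022,-7.3
4,pC+Si+R,FRAP,1000,1925,51,1985,-3.0
4,C+Si+R,FRAP,100,328,10,375,-13
4,C+Si+R,FRAP,500,1617,22,1442,12
4,C+Si+R,FRAP,1000,3214,197,2656,21
4,C+F+Si,FRAP,100,257,5,324,-21
4,C+F+Si,FRAP,500,1044,31,3803,-73
4,C+F+Si,FRAP,1000,2241,30,2005,12
4,C+F+R,FRAP,100,337,9,383,-12
4,C+F+R,FRAP,500,1102,23,4003,-73
4,C+F+R,FRAP,1000,2429,54,2495,-2.7
4,F+Si+R,FRAP,100,314,3,303,3.9
4,F+Si+R,FRAP,500,1331,71,3963,-66
4,F+Si+R,FRAP,1000,2810,43,2516,12
4,pC+C+F+Si,FRAP,100,187,8,249,-25
4,pC+C+F+Si,FRAP,500,741,22,2867,-74
4,pC+C+F+Si,FRAP,1000,1596,44,1532,4.2
4,pC+C+F+R,FRAP,100,224,2,293,-24
4,pC+C+F+R,FRAP,500,967,42,3018,-68
4,pC+C+F+R,FRAP,1000,1917,10,1900,0.9
4,C+F+Si+R,FRAP,100,248,11,346,-28
4,C+F+Si+R,FRAP,500,1164,12,3303,-65
4,C+F+Si+R,FRAP,1000,2576,113,2418,6.5
4,C+Si+R+pC,FRAP,100,245,4,287,-15
4,C+Si+R+pC,FRAP,500,1120,12,1097,2.2
4,C+Si+R+pC,FRAP,1000,2176,24,2020,7.7
4,R+pC+F+Si,FRAP,100,201,11,233,-14
4,R+pC+F+Si,FRAP,500,1064,21,2988,-64
4,R+pC+F+Si,FRAP,1000,1947,36,1915,1.7
4,pC+C+F+Si+R,FRAP,100,247,1,282,-12
4,pC+C+F+Si+R,FRAP,500,1107,39,2655,-58
4,pC+C+F+Si+R,FRAP,1000,2077,35,1957,6.1
5,P+Ge,ORAC,5,150,0.4,55,172
5,P+G,ORAC,5,55,2,43,28
5,P+V,ORAC,5,148,1,56,162
5,P+Sy,ORAC,5,51,0.1,49,4.1
5,Ge+G,ORAC,5,77,5,41,89
5,Ge+V,ORAC,5,150,1,55,174
5,Ge+Sy,ORAC,5,158,2,47,236
5,G+V,ORAC,5,29,0.7,42,-30
5,G+Sy,ORAC,5,26,6,34,-24
5,V+Sy,ORAC,5,149,0.7,48,210
5,P+Ge+G,ORAC,5,56,0.5,46,22
5,P+Ge+V,ORAC,5,82,2,55,48
5,P+Ge+Sy,ORAC,5,69,2,50,38
5,P+G+V,ORAC,5,61,2,47,29
5,P+G+Sy,ORAC,5,43,1,42,1.9
5,P+V+Sy,ORAC,5,65,4,51,27
5,Ge+G+V,ORAC,5,66,4,46,45
5,Ge+G+Sy,ORAC,5,50,2,41,22
5,G+V+Sy,ORAC,5,53,1,41,28
5,V+Sy+Ge,ORAC,5,65,1,50,29
5,P+Ge+G+V,ORAC,5,77,2,49,58
5,P+Ge+V+Sy,ORAC,5,86,4,52,67
5,Ge+G+V+Sy,ORAC,5,67,2,45,50
5,G+V+Sy+P,ORAC,5,65,4,45,44
5,Sy+P+Ge+G,ORAC,5,62,9,45,39
5,P+Ge+G+V+Sy,ORAC,5,60,2,47,27
6,pC+C,ORAC,5,52,2,46,13
6,pC+F,ORAC,5,160,4,39,311
6,pC+Si,ORAC,5,52,3,39,34
6,pC+R,ORAC,5,61,7,63,-2.1
6,C+F,ORAC,5,59,3,49,21
6,C+Si,ORAC,5,162,4,52,211
6,C+R,ORAC,5,163,9,76,115
6,F+Si,ORAC,5,51,4,45,13
6,F+R,ORAC,5,156,1,69,127
6,Si+R,ORAC,5,74,4,68,9
6,pC+C+F,ORAC,5,53,1,46,16
6,pC+C+Si,ORAC,5,47,3,46,2.1
6,pC+C+R,ORAC,5,66,3,62,7.3
6,pC+F+Si,ORAC,5,39,1,41,-4.2
6,pC+F+R,ORAC,5,55,2,57,-3.6
6,pC+Si+R,ORAC,5,54,1,56,-3.7
6,C+Si+R,ORAC,5,56,2,65,-14
6,C+F+Si,ORAC,5,43,3,50,-13
6,C+F+R,ORAC,5,60,2,66,-8.4
6,F+Si+R,ORAC,5,47,2,61,-22
6,pC+C+F+Si,ORAC,5,45,2,45,1.7
6,pC+C+F+R,ORAC,5,56,2,57,-2.9
6,C+F+Si+R,ORAC,5,52,1,60,-14
6,C+Si+R+pC,ORAC,5,52,1,57,-9.2
6,R+pC+F+Si,ORAC,5,77,4,54,44
6,pC+C+F+Si+R,ORAC,5,56,3,55,2.7
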