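# Transcription of the published diagnosed/undiagnosed CKD prevalence
# table, per 100,000 national population, by G stage, 2022 and 2027.
country,status,year,g1,g2,g3a,g3b,g4,g5,total,pct_change_2022_2027
Brazil,diagnosed,2022,67,469,1379,888,139,20,2963,7.8
Brazil,diagnosed,2027,74,430,1677,783,176,55,3193,7.8
Brazil,undiagnosed,2022,1503,1263,3318,661,17,1,6763,10.3
Brazil,undiagnosed,2027,1664,1149,4042,581,21,2,7459,10.3
Canada,diagnosed,2022,133,652,2057,741,256,46,3885,1.1
Canada,diagnosed,2027,144,598,2246,646,203,88,3926,1.1
Canada,undiagnosed,2022,2963,1743,3535,1125,94,0,9460,2.8
Canada,undiagnosed,2027,3216,1598,3852,983,74,0,9723,2.8
Colombia,diagnosed,2022,76,322,915,304,85,11,1713,22.3
Colombia,diagnosed,2027,88,295,1365,249,68,31,2095,22.3
Colombia,undiagnosed,2022,1668,867,2194,227,10,0,4966,12.0
Colombia,undiagnosed,2027,1859,793,2714,184,8,1,5560,12.0
Mexico,diagnosed,2022,190,870,658,418,158,131,2425,0.8
Mexico,diagnosed,2027,215,745,924,364,136,63,2446,0.8
Mexico,undiagnosed,2022,4265,2322,1581,309,19,6,8502,7.9
Mexico,undiagnosed,2027,4725,1947,2212,268,16,3,9171,7.9
USA,diagnosed,2022,229,1036,1268,756,98,17,3404,-0.3
USA,diagnosed,2027,252,896,1373,663,162,48,3394,-0.3
USA,undiagnosed,2022,5098,2774,3043,561,12,1,11488,1.9
USA,undiagnosed,2027,5526,2373,3294,493,19,2,11708,1.9
Belgium,diagnosed,2022,128,657,2081,871,595,131,4463,-5.3
Belgium,diagnosed,2027,141,592,2280,711,340,164,4228,-5.3
Belgium,undiagnosed,2022,2847,1758,3571,1332,215,0,9723,1.1
Belgium,undiagnosed,2027,3128,1577,3917,1082,123,0,9827,1.1
Denmark,diagnosed,2022,134,673,2233,766,243,37,4087,-2.6
Denmark,diagnosed,2027,151,601,2494,529,137,69,3981,-2.6
Denmark,undiagnosed,2022,2913,1803,3824,1172,89,0,9801,-2.0
Denmark,undiagnosed,2027,3228,1605,3910,812,49,0,9605,-2.0
France,diagnosed,2022,155,635,1244,431,241,111,2817,7.3
France,diagnosed,2027,173,528,1647,356,217,102,3023,7.3
France,undiagnosed,2022,3429,1692,2134,657,85,2,7999,4.9
France,undiagnosed,2027,3795,1407,2578,535,72,2,8389,4.9
Germany,diagnosed,2022,359,445,739,243,83,14,1884,11.1
Germany,diagnosed,2027,349,448,991,209,73,24,2093,11.1
Germany,undiagnosed,2022,7967,1193,1269,366,30,0,10825,1.4
Germany,undiagnosed,2027,7719,1206,1707,315,26,0,10972,1.4
Greece,diagnosed,2022,92,163,2328,544,186,32,3345,11.3
Greece,diagnosed,2027,106,148,2865,431,114,60,3723,11.3
Greece,undiagnosed,2022,1535,1820,3989,825,67,0,8236,3.7
Greece,undiagnosed,2027,1766,1642,4443,652,41,0,8544,3.7
Hungary,diagnosed,2022,136,683,1749,1021,242,28,3858,-7.1
Hungary,diagnosed,2027,153,599,2021,640,119,54,3585,-7.1
Hungary,undiagnosed,2022,2971,1819,4198,753,29,1,9771,-1.0
Hungary,undiagnosed,2027,3252,1590,4341,472,14,2,9671,-1.0
Italy,diagnosed,2022,88,349,724,362,166,89,1778,6.3
Italy,diagnosed,2027,94,288,976,352,118,62,1890,6.3
Italy,undiagnosed,2022,1974,933,1740,267,20,4,4938,11.6
Italy,undiagnosed,2027,2118,771,2345,259,14,3,5509,11.6
Netherlands,diagnosed,2022,134,754,1720,551,181,28,3369,7.7
Netherlands,diagnosed,2027,151,676,2242,392,116,50,3628,7.7
Netherlands,undiagnosed,2022,2952,2021,2947,840,65,0,8825,4.2
Netherlands,undiagnosed,2027,3263,1812,3476,599,42,0,9192,4.2
Poland,diagnosed,2022,89,688,1682,523,159,24,3165,7.5
Poland,diagnosed,2027,107,641,2177,345,89,42,3401,7.5
Poland,undiagnosed,2022,1961,1856,2889,802,57,0,7565,4.6
Poland,undiagnosed,2027,2348,1724,3285,526,32,0,7916,4.6
Romania,diagnosed,2022,61,332,1384,231,49,6,2063,33.2
Romania,diagnosed,2027,69,262,2160,170,48,39,2748,33.2
Romania,undiagnosed,2022,1326,889,2361,358,19,0,4952,14.6
Romania,undiagnosed,2027,1468,703,3225,262,18,0,5676,14.6
Spain,diagnosed,2022,71,493,2084,522,180,37,3387,9.5
Spain,diagnosed,2027,79,439,2456,525,141,69,3709,9.5
Spain,undiagnosed,2022,1582,1329,3569,797,65,0,7342,9.0
Spain,undiagnosed,2027,1764,1177,4214,794,52,0,8001,9.0
Sweden,diagnosed,2022,458,385,702,554,222,165,2486,-3.6
Sweden,diagnosed,2027,517,321,911,381,141,126,2398,-3.6
Sweden,undiagnosed,2022,1830,1537,2803,548,54,0,6772,3.4
Sweden,undiagnosed,2027,2060,1277,3256,377,32,0,7002,3.4
Türkiye,diagnosed,2022,230,740,729,555,173,75,2502,0.4
Türkiye,diagnosed,2027,253,667,1034,348,161,49,2512,0.4
Türkiye,undiagnosed,2022,5094,1982,1254,847,62,0,9239,5.7
Türkiye,undiagnosed,2027,5604,1789,1778,534,56,0,9761,5.7
UK,diagnosed,2022,128,634,2086,776,267,48,3940,-3.2
UK,diagnosed,2027,140,567,2202,641,188,75,3814,-3.2
UK,undiagnosed,2022,2872,1693,3589,1184,98,0,9437,0.3
UK,undiagnosed,2027,3125,1513,3788,974,69,0,9468,0.3
Australia,diagnosed,2022,152,604,896,216,103,58,2030,7.0
Australia,diagnosed,2027,168,516,1141,219,82,46,2171,7.0
Australia,undiagnosed,2022,3374,1614,1535,327,37,1,6888,6.5
Australia,undiagnosed,2027,3659,1364,1953,331,29,1,7338,6.5
China,diagnosed,2022,267,263,432,84,37,16,1098,-1.6
China,diagnosed,2027,270,248,455,80,19,8,1081,-1.6
China,undiagnosed,2022,5862,701,741,128,13,0,7446,0.9
China,undiagnosed,2027,5950,661,775,123,7,0,7516,0.9
India,diagnosed,2022,151,190,310,111,35,48,846,-2.5
India,diagnosed,2027,157,172,401,67,19,8,825,-2.5
India,undiagnosed,2022,3389,50,953,116,81,20,4610,3.4
India,undiagnosed,2027,3518,455,684,102,7,0,4766,3.4
Israel,diagnosed,2022,401,202,792,527,329,67,2319,-9.4
Israel,diagnosed,2027,420,185,902,375,160,60,2101,-9.4
Israel,undiagnosed,2022,6792,2263,1450,275,31,0,10811,1.5
Israel,undiagnosed,2027,7047,2074,1644,197,16,0,10978,1.5
Japan,diagnosed,2022,94,1717,1999,1710,370,36,5927,9.9
Japan,diagnosed,2027,111,1518,3179,1122,487,97,6514,9.9
Japan,undiagnosed,2022,2086,4609,3434,2599,133,0,12860,7.9
Japan,undiagnosed,2027,2452,4071,5464,1714,174,0,13875,7.9
Philippines,diagnosed,2022,276,137,713,126,48,30,1331,6.4
Philippines,diagnosed,2027,295,117,820,134,28,22,1417,6.4
Philippines,undiagnosed,2022,1608,792,1440,254,44,0,4137,5.3
Philippines,undiagnosed,2027,1721,681,1660,270,25,0,4356,5.3
Saudi Arabia,diagnosed,2022,179,720,1131,593,302,284,3210,15.0
Saudi Arabia,diagnosed,2027,202,673,1441,687,333,355,3692,15.0
Saudi Arabia,undiagnosed,2022,3955,1907,2725,437,37,12,9074,12.2
Saudi Arabia,undiagnosed,2027,4404,1754,3455,510,40,16,10179,12.2
Singapore,diagnosed,2022,859,564,1617,312,141,89,3583,10.6
Singapore,diagnosed,2027,920,546,1888,401,113,95,3964,10.6
Singapore,undiagnosed,2022,5005,3279,3271,628,126,0,12309,7.7
Singapore,undiagnosed,2027,5358,3172,3812,811,102,0,13255,7.7
South Korea,diagnosed,2022,197,771,951,246,119,22,2305,32.3
South Korea,diagnosed,2027,212,699,1628,286,162,64,3051,32.3
South Korea,undiagnosed,2022,4394,2056,1633,376,44,0,8503,16.2
South Korea,undiagnosed,2027,4726,1867,2796,431,59,0,9879,16.2
Taiwan,diagnosed,2022,196,749,935,242,114,21,2258,28.8
Taiwan,diagnosed,2027,208,658,1574,266,146,56,2908,28.8
Taiwan,undiagnosed,2022,4345,2003,1604,370,41,0,8362,14.0
Taiwan,undiagnosed,2027,4606,1762,2703,408,54,0,9532,14.0
Thailand,diagnosed,2022,356,523,2864,743,205,206,4897,11.2
Thailand,diagnosed,2027,407,472,3142,895,263,269,5448,11.2
Thailand,undiagnosed,2022,2071,3039,5777,1497,183,0,12568,7.3
Thailand,undiagnosed,2027,2367,2745,6337,1802,235,0,13486,7.3
UAE Emirati,diagnosed,2022,173,678,1051,471,279,235,2888,20.1
UAE Emirati,diagnosed,2027,205,724,1563,457,303,217,3469,20.1
UAE Emirati,undiagnosed,2022,3764,1827,2482,343,32,10,8457,11.5
UAE Emirati,undiagnosed,2027,4169,1890,3012,318,31,9,9429,11.5
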