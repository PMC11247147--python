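# Transcription of the published table of projected cardiovascular
# complication prevalence in 2027, per 100,000 patients with CKD.
country,heart_failure,myocardial_infarction,stroke,total
Brazil,7595,3107,2825,13527
Canada,9852,6874,9276,26001
Colombia,9678,8132,1709,19519
Mexico,4947,6703,3962,15612
USA,13114,6505,12876,32494
Belgium,6272,6181,4498,16951
Denmark,11979,10753,9710,32442
France,4666,3662,5923,14252
Germany,1307,474,954,2735
Greece,13243,11611,7686,32540
Hungary,25826,5524,9591,40941
Italy,13496,11758,8641,33895
Netherlands,6744,14469,8059,29273
Poland,14501,17762,44838,77101
Romania,13560,15608,38915,68083
Spain,10555,4691,4196,19441
Sweden,11569,5508,8011,25090
Türkiye,5536,2052,2279,9868
UK,4707,4267,7827,16800
Australia,20621,5288,5005,30914
China,4987,13676,9253,27916
India,11259,10878,5228,27365
Israel,3074,2628,2856,8559
Japan,19769,21231,7365,48366
Philippines,13100,13275,8838,35213
Saudi Arabia,6150,3989,1880,12020
Singapore,5829,9499,5914,21243
South Korea,5795,1995,7251,15041
Taiwan,10759,4687,2949,18395
Thailand,6071,16662,6929,29661
UAE Emirati,8017,5816,5068,18902
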