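# Transcription of the published country demographic summary table
# (national population 2022/2027, sex split, reporting age bands).
country,region,population_2022,population_2027,female_pct,male_pct,age_0_17_pct,age_18_34_pct,age_35_64_pct,age_65_plus_pct,change_65_plus_pct
Brazil,Americas,215353588,221142806,50.9,49.1,24.5,26.6,38.6,10.3,22.5
Canada,Americas,38388416,39939039,50.3,49.7,18.9,22.2,39.9,19.0,17.7
Colombia,Americas,51512766,52530216,50.9,49.1,26.2,28.3,35.8,9.7,22.6
Mexico,Americas,131562775,137608574,51.1,48.9,30.2,27.8,33.9,8.1,20.9
USA,Americas,334805268,344100699,50.5,49.5,22.0,23.3,37.3,17.4,14.0
Belgium,Europe,11668276,11817128,50.4,49.6,20.3,20.3,39.5,19.9,11.0
Denmark,Europe,5834952,5942672,50.3,49.7,19.7,22.0,37.8,20.6,7.9
France,Europe,65584514,66323948,51.6,48.4,21.0,19.5,38.1,21.4,8.9
Germany,Europe,83883587,83346306,50.5,49.5,16.9,19.2,41.6,22.3,9.3
Greece,Europe,10316641,10054798,50.9,49.1,16.3,17.5,43.2,23.0,6.5
Hungary,Europe,9606252,9447725,52.4,47.6,17.5,19.9,41.6,21.0,2.7
Italy,Europe,60262779,59555936,51.2,48.8,15.5,17.5,43.1,23.9,7.9
Netherlands,Europe,17211449,17380060,50.1,49.9,18.8,20.9,39.4,20.9,12.0
Poland,Europe,37739779,37314983,51.6,48.4,18.1,19.7,42.2,20.0,11.0
Romania,Europe,19031330,18590731,51.4,48.6,18.7,19.4,41.9,20.1,2.1
Spain,Europe,47865714,48494124,51.0,49.0,17.3,18.3,44.3,20.2,11.9
Sweden,Europe,10218972,10488223,49.9,50.1,21.0,21.2,37.2,20.6,7.0
Türkiye,Europe,85561976,87612953,50.6,49.4,28.0,26.1,36.4,9.6,20.2
UK,Europe,68497913,69771961,50.5,49.5,21.0,21.2,38.8,19.0,9.3
Australia,Asia-Pacific/Middle East,26068793,27406327,50.2,49.8,23.0,22.3,37.9,16.8,15.2
China,Asia-Pacific/Middle East,1448471404,1461797638,48.7,51.3,20.9,22.7,43.6,12.8,18.4
India,Asia-Pacific/Middle East,1406631781,1469338564,48.0,52.0,30.8,28.9,33.3,7.0,19.4
Israel,Asia-Pacific/Middle East,8922893,9582849,50.2,49.8,32.4,23.3,31.6,12.7,12.2
Japan,Asia-Pacific/Middle East,125584839,122754999,51.2,48.8,14.9,16.5,39.7,28.9,1.5
Philippines,Asia-Pacific/Middle East,112508991,119632644,49.8,50.2,34.8,29.2,30.0,5.9,24.9
Saudi Arabia,Asia-Pacific/Middle East,35844913,38115319,42.2,57.8,28.5,26.5,41.2,3.8,39.4
Singapore,Asia-Pacific/Middle East,5943551,6158533,47.7,52.3,14.9,22.5,47.4,15.2,35.8
South Korea,Asia-Pacific/Middle East,51329905,51293519,50.0,50.0,14.8,20.8,47.0,17.4,26.2
Taiwan,Asia-Pacific/Middle East,23888600,23997588,50.4,49.6,15.2,21.3,46.2,17.3,22.4
Thailand,Asia-Pacific/Middle East,70078198,70394102,51.4,48.6,19.6,22.6,43.6,14.2,24.2
UAE Emirati,Asia-Pacific/Middle East,1604749,1749670,23.3,76.7,31.0,29.8,35.7,3.6,122.4
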