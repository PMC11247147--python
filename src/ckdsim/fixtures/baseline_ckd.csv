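# Transcription of the published baseline (2022) CKD demographics table:
# per-G-stage prevalence %, all-stage %, diagnosed %, comorbidity % in CKD.
country,g1_pct,g2_pct,g3a_pct,g3b_pct,g4_pct,g5_pct,ckd_all_stages_pct,ckd_diagnosed_pct,t2d_in_ckd_pct,htn_in_ckd_pct
Brazil,1.57,1.73,4.7,1.55,0.16,0.02,9.73,2.96,36.0,78.6
Canada,3.1,2.39,5.59,1.87,0.35,0.05,13.34,3.88,32.2,56.9
Colombia,1.74,1.19,3.11,0.53,0.1,0.01,6.68,1.71,33.1,77.4
Mexico,4.46,3.19,2.24,0.73,0.18,0.14,10.93,2.43,43.1,79.8
USA,5.33,3.81,4.31,1.32,0.11,0.02,14.89,3.4,29.5,62.9
Belgium,2.97,2.42,5.65,2.2,0.81,0.13,14.19,4.28,19.9,55.8
Denmark,3.05,2.48,6.06,1.94,0.33,0.04,13.89,4.05,19.4,55.4
France,3.58,2.33,3.38,1.09,0.33,0.11,10.82,3.06,19.9,52.7
Germany,8.33,1.64,2.01,0.61,0.11,0.01,12.71,2.08,20.0,48.1
Greece,1.63,1.98,6.32,1.37,0.25,0.03,11.58,3.63,19.6,57.8
Hungary,3.11,2.5,5.95,1.77,0.27,0.03,13.63,3.53,27.8,72.6
Italy,2.06,1.28,2.46,0.63,0.19,0.09,6.72,1.78,35.1,77.8
Netherlands,3.09,2.78,4.67,1.39,0.25,0.03,12.19,3.37,19.7,55.4
Poland,2.05,2.54,4.57,1.33,0.22,0.02,10.73,3.17,20.0,57.3
Romania,1.39,1.22,3.75,0.59,0.07,0.01,7.02,2.06,27.0,72.0
Spain,1.65,1.82,5.65,1.32,0.24,0.04,10.73,3.39,31.9,77.2
Sweden,2.29,1.92,3.51,1.1,0.28,0.17,9.26,2.49,33.8,62.8
Türkiye,5.32,2.72,1.98,1.4,0.23,0.08,11.74,2.5,20.9,52.8
UK,3.0,2.33,5.68,1.96,0.36,0.05,13.38,3.94,19.8,55.3
Australia,3.53,2.22,2.43,0.54,0.14,0.06,8.92,2.03,20.6,52.5
China,6.13,0.96,1.17,0.21,0.05,0.02,8.54,1.1,20.8,49.9
India,3.54,0.7,0.84,0.28,0.05,0.05,5.46,0.85,30.0,65.1
Israel,7.19,2.47,2.24,0.8,0.36,0.07,13.13,2.32,37.7,44.7
Japan,2.18,6.33,5.43,4.31,0.5,0.04,18.79,5.93,19.9,54.6
Philippines,1.88,0.93,2.15,0.38,0.09,0.03,5.47,1.33,22.3,66.6
Saudi Arabia,4.13,2.63,3.86,1.03,0.34,0.3,12.28,3.21,28.2,60.6
Singapore,5.86,3.84,4.89,0.94,0.27,0.09,15.89,3.58,20.7,53.6
South Korea,4.59,2.83,2.58,0.62,0.16,0.02,10.81,2.31,20.7,52.5
Taiwan,4.54,2.75,2.54,0.61,0.16,0.02,10.62,2.26,42.0,66.2
Thailand,2.43,3.56,8.64,2.24,0.39,0.21,17.46,4.9,20.0,57.5
UAE Emirati,3.94,2.51,3.53,0.81,0.31,0.25,11.35,2.89,28.0,60.8
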