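cohort,region,n,prevalence,severity,patterns,age_mean,age_sd,pct_women,pct_edentulous,teeth_mean,teeth_sd,cases,prevalence_pct,dmft_mean,dmft_sd,dmfs_mean,dmfs_sd,c1_mean,c1_sd,c2_mean,c2_sd,c3_mean,c3_sd,c4_mean,c4_sd,c5_mean,c5_sd
SIMPLER,Sweden,19052,1,1,1,73.6,8.0,33.7,1.4,23.2,6.3,17416,91.4,14.8,8.8,55.0,35.4,0.65,0.35,0.14,0.28,0.58,0.33,0.39,0.38,0.38,0.32
TWINGENE/STR,Sweden,16849,1,1,1,48.7,19.0,58.2,0.3,26.0,3.9,15893,94.3,12.3,7.9,35.7,31.4,0.56,0.35,0.06,0.18,0.40,0.33,0.21,0.30,0.22,0.27
MDC/MOS,Sweden,11176,1,1,1,67.9,17.9,63.4,0.9,23.6,5.9,10874,97.3,17.8,7.5,62.9,34.2,0.74,0.31,0.17,0.28,0.65,0.32,0.45,0.38,0.46,0.33
VIKING,Sweden,3823,1,1,1,63.8,8.0,63.4,0.9,24.7,4.9,3772,98.7,17.3,7.8,55.9,31.7,0.73,0.31,0.13,0.23,0.60,0.31,0.38,0.34,0.37,0.30
CCDG: COHRA1/Dental SCORE,United States,1810,1,1,1,43.8,15.7,64.6,5.1,23.1,7.2,1763,97.4,13.7,7.3,44.1,34.3,0.73,0.28,0.10,0.25,0.46,0.34,0.29,0.37,0.26,0.31
CCDG: COHRA2/COHRA Smile,United States,1185,1,1,1,32.4,6.2,100,0.7,26.4,3.7,1109,93.6,8.7,6.4,22.7,23.7,0.53,0.33,0.03,0.12,0.24,0.46,0.13,0.25,0.11,0.20
Periogene North,Sweden,995,1,1,1,49.0,13.1,57.6,0,25.6,3.8,951,95.6,12.0,7.5,34.1,29.8,0.58,0.32,0.07,0.18,0.38,0.31,0.20,0.30,0.19,0.26
IFS,United States,253,1,1,1,22.7,1.8,56.5,0,24.7,2.9,243,96.0,4.0,3.3,7.1,8.9,0.23,0.24,0.01,0.04,0.05,0.09,0.03,0.09,0.05,0.12
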