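cohort,region,n,prevalence,severity,patterns,notes
ARIC,United States,5527,1,1,0,tooth-level data only
CCDG: COHRA1/Dental SCORE,United States,1810,1,1,1,
CCDG: COHRA2/COHRA Smile,United States,1185,1,1,1,
CCDG: OFC1/OFC2,"Africa, Asia, Europe, North America, South America",4967,1,1,0,tooth-level data only; intraoral photographs
EstBB,Estonia,~200000,1,0,0,
FinnGen,Finland,~390000,1,1,0,tooth-level data only
Generation Scotland,Scotland,~18000,1,0,0,
Health 2000/2011,Finland,7831,1,1,0,tooth-level data only
HUNT4,Norway,4933,1,1,1,
IFS,United States,253,1,1,1,
MDC/MOS,Sweden,11176,1,1,1,
NFBC1966,Finland,1483,1,1,0,
Parogene,Finland,508,1,1,0,tooth-level data only
Periogene North,Sweden,995,1,1,1,
SHIP START,Germany,3362,1,1,0,half-mouth clinical examinations
SHIP TREND,Germany,944,1,1,1,half-mouth clinical examinations
SIMPLER,Sweden,19052,1,1,1,
SOL,United States,11816,1,1,1,
TWINGENE/STR,Sweden,16849,1,1,1,
ToMMo,Japan,5360,1,0,0,
VIKING,Sweden,3823,1,1,1,
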