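name,rho,sigma,eps_r,c,k,perfusion
POM,1150,2.7e-5,3.6,1670,0.230,
Parylene C,1289,1e-5,2.4,712,0.084,
Air,1.164,0,1,1004,0.0273,
Muscle,1090.4,0.654,95.764,3421,0.495,39.74
Fat,911,0.061,17.928,2348,0.211,32.71
Prostate,1045,0.838,120.056,3760,0.512,394.12
Rectum,1045,0.654,95.8,3801,0.557,0
Urethra,1102,0.375,88.8,3306,0.462,394
Bladder,1086,0.276,31.5,3581,0.522,78
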