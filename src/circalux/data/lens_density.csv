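# Crystalline lens optical density, average young adult observer
# (Wyszecki & Stiles-type tabulation after van Norren & Vos).
# Transmittance is 10^(-density).
# columns: wavelength_nm, optical_density
380,1.90
390,1.40
400,1.00
410,0.72
420,0.51
430,0.40
440,0.34
450,0.28
460,0.24
470,0.20
480,0.17
490,0.14
500,0.12
510,0.105
520,0.090
530,0.080
540,0.070
550,0.060
560,0.055
570,0.050
580,0.045
590,0.040
600,0.035
610,0.032
620,0.029
630,0.026
640,0.024
650,0.021
660,0.019
670,0.017
680,0.015
690,0.013
700,0.012
710,0.011
720,0.010
730,0.009
740,0.008
750,0.007
760,0.006
770,0.005
780,0.005
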