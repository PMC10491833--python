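# Melanopic action spectrum s_mel(lambda), energy-based, peak-normalized,
# after CIE S 026:2018 (10 nm tabulation; finer grids by linear interpolation).
# columns: wavelength_nm, value
380,0.00091
390,0.00241
400,0.00783
410,0.02106
420,0.08471
430,0.19313
440,0.31884
450,0.43899
460,0.68569
470,0.85093
480,0.96044
490,1.00000
500,0.96161
510,0.81700
520,0.65831
530,0.51605
540,0.39333
550,0.29061
560,0.20848
570,0.14409
580,0.09690
590,0.06338
600,0.04040
610,0.02540
620,0.01556
630,0.00950
640,0.00570
650,0.00340
660,0.00200
670,0.00120
680,0.00070
690,0.00040
700,0.00025
710,0.00015
720,0.00009
730,0.00005
740,0.00003
750,0.00002
760,0.00001
770,0.00001
780,0.000004
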