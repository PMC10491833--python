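# Macular pigment relative optical density (Snodderly-type, 2-degree field),
# peak-normalized to 1 at 460 nm. Transmittance is 10^(-D_peak * value) with the
# peak density D_peak applied at load time (default 0.35).
# columns: wavelength_nm, relative_density
380,0.10
385,0.11
390,0.12
395,0.14
400,0.20
405,0.26
410,0.33
415,0.39
420,0.46
425,0.52
430,0.58
435,0.65
440,0.72
445,0.80
450,0.87
455,0.94
460,1.00
465,0.99
470,0.92
475,0.84
480,0.74
485,0.61
490,0.49
495,0.37
500,0.24
505,0.16
510,0.10
515,0.06
520,0.035
525,0.020
530,0.010
535,0.005
540,0.000
545,0.000
550,0.000
560,0.000
580,0.000
600,0.000
650,0.000
700,0.000
780,0.000
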