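# S-cone fundamental, Smith-Pokorny construction: proportional to the
# zbar colour-matching function (S = 0.00801*zbar convention), here peak-normalized
# columns: wavelength_nm, value
380,0.003618
385,0.005918
390,0.011248
395,0.020313
400,0.038062
405,0.061820
410,0.116347
415,0.208291
420,0.362168
425,0.582885
430,0.777292
435,0.910445
440,0.980063
445,1.000000
450,0.994115
455,0.978402
460,0.936385
465,0.857231
470,0.722338
475,0.584483
480,0.456047
485,0.345675
490,0.260956
495,0.198194
500,0.152586
505,0.119096
510,0.088747
515,0.062661
520,0.043897
525,0.032116
530,0.023651
535,0.016740
540,0.011388
545,0.007517
550,0.004909
555,0.003226
560,0.002188
565,0.001543
570,0.001178
575,0.001010
580,0.000926
585,0.000785
590,0.000617
595,0.000561
600,0.000449
605,0.000337
610,0.000191
615,0.000135
620,0.000107
625,0.000056
630,0.000028
635,0.000017
640,0.000011
645,0.000006
650,0.000000
655,0.000000
660,0.000000
665,0.000000
670,0.000000
675,0.000000
680,0.000000
685,0.000000
690,0.000000
695,0.000000
700,0.000000
705,0.000000
710,0.000000
715,0.000000
720,0.000000
725,0.000000
730,0.000000
735,0.000000
740,0.000000
745,0.000000
750,0.000000
755,0.000000
760,0.000000
765,0.000000
770,0.000000
775,0.000000
780,0.000000
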