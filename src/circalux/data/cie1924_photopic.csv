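# CIE 1924 photopic luminous efficiency function V(lambda)
# columns: wavelength_nm, value (peak-normalized, maximum 1 at 555 nm)
# identical to the ybar colour-matching function of the CIE 1931 2-degree observer
380,0.000039
385,0.000064
390,0.000120
395,0.000217
400,0.000396
405,0.000640
410,0.001210
415,0.002180
420,0.004000
425,0.007300
430,0.011600
435,0.016840
440,0.023000
445,0.029800
450,0.038000
455,0.048000
460,0.060000
465,0.073900
470,0.090980
475,0.112600
480,0.139020
485,0.169300
490,0.208020
495,0.258600
500,0.323000
505,0.407300
510,0.503000
515,0.608200
520,0.710000
525,0.793200
530,0.862000
535,0.914850
540,0.954000
545,0.980300
550,0.994950
555,1.000000
560,0.995000
565,0.978600
570,0.952000
575,0.915400
580,0.870000
585,0.816300
590,0.757000
595,0.694900
600,0.631000
605,0.566800
610,0.503000
615,0.441200
620,0.381000
625,0.321000
630,0.265000
635,0.217000
640,0.175000
645,0.138200
650,0.107000
655,0.081600
660,0.061000
665,0.044580
670,0.032000
675,0.023200
680,0.017000
685,0.011920
690,0.008210
695,0.005723
700,0.004102
705,0.002929
710,0.002091
715,0.001484
720,0.001047
725,0.000740
730,0.000520
735,0.000361
740,0.000249
745,0.000172
750,0.000120
755,0.000085
760,0.000060
765,0.000042
770,0.000030
775,0.000021
780,0.000015
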