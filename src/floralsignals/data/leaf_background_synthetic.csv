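wavelength_nm,value
300,0.0450
305,0.0450
310,0.0450
315,0.0450
320,0.0450
325,0.0450
330,0.0450
335,0.0450
340,0.0450
345,0.0450
350,0.0450
355,0.0450
360,0.0450
365,0.0450
370,0.0450
375,0.0450
380,0.0450
385,0.0450
390,0.0450
395,0.0450
400,0.0450
405,0.0450
410,0.0450
415,0.0450
420,0.0450
425,0.0450
430,0.0451
435,0.0451
440,0.0452
445,0.0453
450,0.0456
455,0.0459
460,0.0465
465,0.0473
470,0.0485
475,0.0502
480,0.0526
485,0.0558
490,0.0599
495,0.0651
500,0.0715
505,0.0791
510,0.0877
515,0.0973
520,0.1076
525,0.1180
530,0.1280
535,0.1372
540,0.1450
545,0.1507
550,0.1541
555,0.1549
560,0.1531
565,0.1487
570,0.1421
575,0.1337
580,0.1241
585,0.1138
590,0.1034
595,0.0934
600,0.0841
605,0.0759
610,0.0688
615,0.0629
620,0.0581
625,0.0543
630,0.0514
635,0.0490
640,0.0469
645,0.0447
650,0.0420
655,0.0389
660,0.0356
665,0.0330
670,0.0320
675,0.0333
680,0.0373
685,0.0439
690,0.0531
695,0.0656
700,0.0827
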