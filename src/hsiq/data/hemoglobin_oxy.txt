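# oxygenated whole blood mu_a [mm^-1 per blood volume fraction], 150 g Hb/L
# wavelength_nm  value
400.0 142.465
405.0 187.453
410.0 249.581
414.0 278.502
418.0 257.079
422.0 193.88
426.0 128.54
430.0 80.3372
432.0 64.2698
435.0 49.2735
440.0 32.1349
445.0 29.9926
450.0 29.457
460.0 17.1386
470.0 12.854
480.0 10.7116
490.0 10.4438
500.0 11.1401
510.0 12.854
520.0 16.0674
530.0 22.4944
540.0 28.3858
542.0 28.9214
545.0 27.8502
550.0 23.03
555.0 19.8165
560.0 17.6742
565.0 19.2809
570.0 24.1012
575.0 29.9926
577.0 30.5281
580.0 27.8502
585.0 18.7453
590.0 8.03372
600.0 1.71386
610.0 0.85693
620.0 0.535581
630.0 0.374907
640.0 0.267791
650.0 0.214233
660.0 0.171386
670.0 0.160674
680.0 0.155319
690.0 0.160674
700.0 0.171386
710.0 0.187453
720.0 0.214233
730.0 0.235656
740.0 0.257079
750.0 0.283858
760.0 0.321349
770.0 0.353484
780.0 0.385619
790.0 0.412398
800.0 0.437034
810.0 0.471312
820.0 0.508802
840.0 0.56236
860.0 0.615919
880.0 0.642698
900.0 0.669477
950.0 0.696256
1000.0 0.642698
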