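# deoxygenated whole blood mu_a [mm^-1 per blood volume fraction], 150 g Hb/L
# wavelength_nm  value
400.0 119.435
405.0 133.895
410.0 155.319
414.0 171.386
418.0 188.525
422.0 224.944
426.0 257.079
430.0 283.858
432.0 285.465
435.0 273.147
440.0 214.233
445.0 155.319
450.0 55.7005
460.0 29.457
470.0 18.2098
480.0 14.4607
490.0 12.854
500.0 12.0506
510.0 12.3184
520.0 13.9251
530.0 17.6742
540.0 22.4944
542.0 23.5656
545.0 25.1723
550.0 27.3147
555.0 28.3858
560.0 27.8502
565.0 26.7791
570.0 25.7079
575.0 24.9045
577.0 24.6367
580.0 22.4944
585.0 20.3521
590.0 17.6742
600.0 9.37267
610.0 4.82023
620.0 3.48128
630.0 2.73147
640.0 2.35656
650.0 2.03521
660.0 1.72832
670.0 1.49963
680.0 1.36573
690.0 1.23184
700.0 1.07116
710.0 0.990826
720.0 0.910488
730.0 0.85693
740.0 0.830151
750.0 0.85693
760.0 0.894421
770.0 0.803372
780.0 0.723035
790.0 0.58914
800.0 0.465956
810.0 0.439177
820.0 0.417753
840.0 0.385619
860.0 0.374907
880.0 0.374907
900.0 0.401686
950.0 0.428465
1000.0 0.482023
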