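# melanosome interior mu_a [mm^-1 per melanosome volume fraction]
# wavelength_nm  value
400.0 142.786
405.0 136.999
410.0 131.515
415.0 126.312
420.0 121.373
425.0 116.683
430.0 112.226
435.0 107.988
440.0 103.955
445.0 100.116
450.0 96.4598
455.0 92.975
460.0 89.6521
465.0 86.482
470.0 83.4561
475.0 80.5664
480.0 77.8056
485.0 75.1664
490.0 72.6425
495.0 70.2277
500.0 67.9163
505.0 65.7028
510.0 63.5822
515.0 61.5497
520.0 59.6009
525.0 57.7316
530.0 55.9378
535.0 54.2158
540.0 52.5621
545.0 50.9734
550.0 49.4466
555.0 47.9787
560.0 46.567
565.0 45.2088
570.0 43.9016
575.0 42.6432
580.0 41.4313
585.0 40.2638
590.0 39.1387
595.0 38.0542
600.0 37.0084
605.0 35.9997
610.0 35.0264
615.0 34.0871
620.0 33.1802
625.0 32.3045
630.0 31.4586
635.0 30.6413
640.0 29.8514
645.0 29.0877
650.0 28.3493
655.0 27.6351
660.0 26.944
665.0 26.2753
670.0 25.628
675.0 25.0013
680.0 24.3944
685.0 23.8064
690.0 23.2368
695.0 22.6848
700.0 22.1497
705.0 21.6309
710.0 21.1278
715.0 20.6398
720.0 20.1663
725.0 19.7069
730.0 19.261
735.0 18.8281
740.0 18.4078
745.0 17.9996
750.0 17.6031
755.0 17.2179
760.0 16.8436
765.0 16.4798
770.0 16.1261
775.0 15.7823
780.0 15.4479
785.0 15.1227
790.0 14.8063
795.0 14.4984
800.0 14.1989
805.0 13.9073
810.0 13.6235
815.0 13.3472
820.0 13.0781
825.0 12.816
830.0 12.5607
835.0 12.312
840.0 12.0696
845.0 11.8334
850.0 11.6032
855.0 11.3788
860.0 11.16
865.0 10.9466
870.0 10.7385
875.0 10.5355
880.0 10.3375
885.0 10.1443
890.0 9.95578
895.0 9.77177
900.0 9.59216
905.0 9.41682
910.0 9.24562
915.0 9.07845
920.0 8.91519
925.0 8.75572
930.0 8.59995
935.0 8.44775
940.0 8.29905
945.0 8.15372
950.0 8.01169
955.0 7.87286
960.0 7.73714
965.0 7.60445
970.0 7.47471
975.0 7.34782
980.0 7.22372
985.0 7.10234
990.0 6.98359
995.0 6.86741
1000.0 6.75373
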