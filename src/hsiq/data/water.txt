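# pure water mu_a [mm^-1 per water volume fraction]
# wavelength_nm  value
400.0 5.8e-06
420.0 4.5e-06
440.0 6.3e-06
460.0 8.9e-06
480.0 1.27e-05
500.0 2.04e-05
520.0 4.09e-05
540.0 4.74e-05
560.0 6.19e-05
580.0 8.96e-05
600.0 0.0002224
620.0 0.0002644
640.0 0.0003292
660.0 0.0004064
680.0 0.000465
700.0 0.000624
720.0 0.00104
740.0 0.00224
750.0 0.00247
760.0 0.00255
780.0 0.00235
800.0 0.002
820.0 0.0024
840.0 0.0035
860.0 0.0046
880.0 0.0056
900.0 0.0068
920.0 0.013
940.0 0.027
960.0 0.042
970.0 0.045
980.0 0.043
1000.0 0.036
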