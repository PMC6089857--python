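amine-BF3 adduct
  benchchem

  7  6  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 N   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 B   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8700    0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.8700   -0.5000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.8700    0.5000    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
    1.8700   -0.5000    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000   -1.0000    0.0000 F   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  9  0
  1  3  1  0
  1  4  1  0
  2  5  1  0
  2  6  1  0
  2  7  1  0
M  ISO  1   4  13
M  END
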