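
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 K    -1   2   0  -1  -3   1   1  -2  -1  -3  -3   5  -2  -3  -1   0  -1  -3  -2  -3    0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0  0.51 0.00
    2 E    -2  -1  -1   1  -3   1   4  -3  -1  -3  -3   0  -2  -1  -2  -1  -1   8   0  -3    0   0   0   0   0   0  66   0   0   0   0   0   0   0   0   0   0  34   0   0  0.83 0.00
    3 G     0  -3   0  -1  -3  -2  -2   6  -2  -4  -4  -2  -3  -3  -2   0  -2  -3  -3  -4    0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0  1.04 0.01
    4 G     0  -3   0  -1  -3  -2  -2   6  -2  -4  -4  -2  -3  -3  -2   0  -2  -3  -3  -4    0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0  1.04 0.01
    5 I    -1  -3  -4  -4  -1  -3  -4  -4  -4   4   2  -3   1   0  -3  -3  -1  -3  -1   3    0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0  0.38 0.01
    6 S     1  -1   1   0  -1   0   0   0  -1  -3  -3   0  -2  -3  -1   4   2  -3  -2  -2    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0  0.45 0.00
    7 D    -2  -2   1   6  -4   0   2  -1  -1  -4  -4  -1  -3  -4  -2   0  -1  -5  -3  -4    0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.92 0.00
    8 H    -2   0   1  -1  -3   0   0  -2   8  -4  -3  -1  -2  -1  -2  -1  -2  -3   2  -4    0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0  0.84 0.00
    9 R    -2   6   0  -2  -4   1   0  -3   0  -3  -2   2  -2  -3  -2  -1  -1  -3  -2  -3    0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.74 0.00
   10 R    -2   6   0  -2  -4   1   0  -3   0  -3  -2   2  -2  -3  -2  -1  -1  -3  -2  -3    0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.74 0.00
   11 L    -2  -2  -4  -4  -1  -2  -3  -4  -3   2   4  -3   2   0  -3  -3  -1  -2  -1   1    0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0  0.45 0.01
   12 D    -2  -2   0   5  -3  -1   1  -2  -2   1  -1  -1  -1  -2  -2  -1  -1  -4  -3   0    0   0   0  66   0   0   0   0   0  34   0   0   0   0   0   0   0   0   0   0  0.42 0.01
   13 H    -2   0   1  -1  -3   0   0  -2   8  -4  -3  -1  -2  -1  -2  -1  -2  -3   2  -4    0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0  0.84 0.00
   14 V     0  -3  -3  -4  -1  -2  -3  -4  -4   3   1  -3   1  -1  -3  -2   0  -3  -1   4    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100  0.34 0.01
   15 Y    -2  -2  -2  -3  -3  -2  -2  -3   1  -2  -2  -2  -2   2   5  -2  -2   1   6  -2    0   0   0   0   0   0   0   0   0   0   0   0   0   0  34   0   0   0  66   0  0.81 0.00
   16 P    -1  -2  -2  -2  -3  -1  -1  -2  -2  -3  -3  -1  -3  -4   8  -1  -1  -4  -3  -3    0   0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0  2.04 0.00
   17 D    -2  -2   1   6  -4   0   2  -1  -1  -4  -4  -1  -3  -4  -2   0  -1  -5  -3  -4    0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.92 0.00
   18 V    -1  -3  -3  -4  -1  -3  -3  -4  -4   4   1  -3   1  -1  -3  -2   0  -3  -1   4    0   0   0   0   0   0   0   0   0  34   0   0   0   0   0   0   0   0   0  66  0.34 0.01
   19 D    -2  -2   1   6  -4   0   2  -1  -1  -4  -4  -1  -3  -4  -2   0  -1  -5  -3  -4    0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.92 0.00
   20 H    -2   0   1  -1  -3   0   0  -2   8  -4  -3  -1  -2  -1  -2  -1  -2  -3   2  -4    0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0  0.84 0.00
   21 D    -2  -2   1   6  -4   0   2  -1  -1  -4  -4  -1  -3  -4  -2   0  -1  -5  -3  -4    0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.92 0.00
   22 E    -1   0   0   2  -4   2   6  -2   0  -4  -3   1  -2  -4  -1   0  -1  -3  -2  -3    0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0  0.73 0.00
   23 A     4  -2  -2  -2   0  -1  -1   0  -2  -1  -2  -1  -1  -2  -1   1   0  -3  -2   0  100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.40 0.01
   24 H    -2   0   1  -1  -3   0   0  -2   8  -4  -3  -1  -2  -1  -2  -1  -2  -3   2  -4    0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0   0  0.84 0.00
   25 W    -3  -3  -4  -5  -3  -2  -3  -3  -3  -3  -2  -3  -2   1  -4  -3  -3  12   2  -3    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0 100   0   0  2.29 0.00
   26 D    -2  -2   1   6  -4   0   2  -1  -1  -4  -4  -1  -3  -4  -2   0  -1  -5  -3  -4    0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.92 0.00
   27 I    -1  -3  -4  -4  -1  -3  -4  -4  -4   4   2  -3   1   0  -3  -3  -1  -3  -1   3    0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0   0   0   0  0.38 0.01
   28 A     4  -2  -2  -2   0  -1  -1   0  -2  -1  -2  -1  -1  -2  -1   1   0  -3  -2   0  100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.40 0.01
   29 I    -1  -1  -2  -2  -2   3   0  -3  -2   3   1  -1   1  -1  -2  -2  -1  -3  -2   2    0   0   0   0   0  34   0   0   0  66   0   0   0   0   0   0   0   0   0   0  0.19 0.01
   30 D    -2  -2   1   6  -4   0   2  -1  -1  -4  -4  -1  -3  -4  -2   0  -1  -5  -3  -4    0   0   0 100   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  0.92 0.00

                      K         Lambda
Standard Ungapped    0.1424     0.3186
Standard Gapped      0.0459     0.2670
PSI Ungapped         0.1500     0.3190
PSI Gapped           0.0459     0.2670
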