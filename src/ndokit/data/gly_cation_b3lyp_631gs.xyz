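11
glycine cation optimized at B3LYP/6-31G* (built-in engine), E = -284.77951735 hartree
N     -1.37624309      0.24090340     -0.22402020
C     -0.21922980     -0.48153205      0.42150884
C      1.05010386      0.16376909     -0.13268455
O      0.98984322      1.07275601     -0.92925480
O      2.13087301     -0.40495018      0.37524367
H     -1.32728099      1.24853828     -0.02176431
H     -1.31661542      0.16994792     -1.24872695
H     -2.28673540     -0.12048830      0.08552502
H     -0.29378952     -0.36746579      1.50551491
H     -0.28111108     -1.54242248      0.16800917
H      2.93065992      0.02356008      0.00707747
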