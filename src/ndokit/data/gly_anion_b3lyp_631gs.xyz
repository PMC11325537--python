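9
glycine anion optimized at B3LYP/6-31G* (built-in engine), E = -283.85079116 hartree
N     -1.38200494      0.17446103     -0.22234067
C     -0.10466019     -0.57668494     -0.21605138
C      1.14498055      0.28507153      0.19689063
O      2.19314689     -0.35989344      0.43359904
O      0.94425796      1.53254671      0.20433163
H     -1.03170759      1.13538697     -0.35115933
H     -1.69544432      0.20313123      0.75206511
H     -0.17693225     -1.45615647      0.43692391
H      0.08228124     -0.96809613     -1.22909255
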