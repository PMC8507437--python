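owt,b443,b490,b560,b665,b708,b778,b865
1,0.004434,0.005231,0.002362,6.2e-05,6e-06,0.0,0.0
2,0.005698,0.007811,0.005381,0.000438,0.000115,0.000146,0.000109
3,0.006505,0.009801,0.009055,0.001612,0.000516,0.000315,0.000219
4,0.007001,0.011203,0.012701,0.003979,0.001618,0.000601,0.000332
5,0.007292,0.012127,0.015891,0.00756,0.003803,0.001241,0.00047
6,0.007449,0.012693,0.018456,0.012023,0.007189,0.002572,0.000709
7,0.007518,0.013004,0.020391,0.016885,0.01159,0.004897,0.001219
8,0.007529,0.01314,0.021772,0.021696,0.016629,0.008339,0.002249
9,0.007504,0.013155,0.022699,0.026134,0.021884,0.012808,0.004061
10,0.007454,0.013091,0.023273,0.030012,0.026993,0.018047,0.006838
11,0.007388,0.012976,0.023579,0.033257,0.031703,0.023724,0.01063
12,0.007313,0.012828,0.023688,0.035873,0.035862,0.02951,0.015346
13,0.007233,0.012661,0.023655,0.037908,0.039408,0.035128,0.020787
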