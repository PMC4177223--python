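individual_id,phenotype,sex,nh,str,mtdna,x1,x2,y
bLge01,Lge,M,0.994,0.984,Lgut,Lge,,Lge
bLge02,Lge,M,0.316,0.924,Lgut,Lgut,,Lgut
bLge04,Lge,M,0.036,0.883,Lge,Lgut,,Lgut
bLge05,Lge,M,0.001,0.807,Lge,Lgut,,Lge
bLge06,Lge,U,0.172,0.697,Lgut,,,
bLge07,Lge,M,0.000,0.140,Lgut,Lgut,,Lge
bLge08,Lge,M,0.006,0.756,Lgut,Lgut,,Lge
bLge10,Lge,F,0.951,0.974,Lge,Lgut,,
bLge11,Lge,M,0.015,0.792,Lgut,Lge,,Lge
bLge12,Lge,M,0.963,0.971,Lge,Lgut,,Lgut
bLge13,Lge,M,0.000,0.340,Lgut,Lgut,,Lgut
bLge32,Lge,M,0.011,0.787,Lge,Lgut,,Lge
bLge42,Lge,M,0.004,0.706,Lge,Lgut,,Lgut
bLge46,Lge,M,0.001,0.631,Lgut,Lge,,Lgut
bLge49,Lge,M,0.712,0.932,Lge,Lgut,,Lgut
bLge72,Lge,M,0.000,0.265,Lgut,,,Lgut
bLge73,Lge,M,0.000,0.483,Lge,Lgut,,Lge
bLge74,Lge,F,0.000,0.131,Lgut,Lge,,
bLge76,Lge,M,0.038,0.773,Lge,Lge,,Lge
bLge79,Lge,M,0.071,0.887,Lgut,Lgut,,Lgut
bLge80,Lge,M,0.990,0.985,Lgut,Lge,,Lgut
bLge90,Lge,M,0.036,0.520,Lge,Lge,,Lgut
bLge93,Lge,F,0.000,0.105,Lgut,Lge,,
bLgut01,Lgut,F,0.018,0.635,Lge,Lgut,,
bLgut05,Lgut,M,0.760,0.923,Lgut,Lge,,Lge
bLgut09,Lgut,F,0.001,0.247,Lge,Lgut,,
bLgut47,Lgut,F,0.249,0.676,Lgut,Lgut,,
bLgut49,Lgut,F,0.000,0.054,Lge,Lgut,,
bLgut68,Lgut,M,0.961,0.958,Lgut,Lge,,Lgut
bLgut79,Lgut,F,0.000,0.098,Lge,Lgut,Lge,
bLgut98,Lgut,F,0.000,0.068,Lgut,Lgut,,
bLgut108,Lgut,M,0.031,0.734,Lgut,Lgut,,Lgut
bLgut119,Lgut,M,0.000,0.191,Lgut,,,Lge
bLgut121,Lgut,M,0.000,0.078,Lge,Lgut,,Lgut
bLgut135,Lgut,F,0.000,0.158,Lgut,Lgut,,
bLgut138,Lgut,F,0.194,0.268,Lgut,Lgut,,
bLgut141,Lgut,M,0.002,0.443,Lgut,,,Lgut
bLgut143,Lgut,F,0.862,0.943,Lgut,Lgut,Lge,
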