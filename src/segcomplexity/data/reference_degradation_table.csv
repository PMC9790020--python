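dataset,de,mnf,mdf,pc,factor,se,sp,a,ba,dice,jaccard,error
STARE,0.2105,0.3725,0.1796,0.1971,2,0.8741,0.9915,0.9826,0.9328,0.8833,0.7913,0.2087
STARE,0.2105,0.3725,0.1796,0.1971,3,0.8086,0.9872,0.9738,0.8979,0.8226,0.6991,0.3009
STARE,0.2105,0.3725,0.1796,0.1971,4,0.7586,0.9868,0.9696,0.8727,0.7895,0.6527,0.3473
DRIVE,0.2821,0.4632,0.2301,0.2253,2,0.8077,0.9872,0.9715,0.8975,0.8317,0.7121,0.2879
DRIVE,0.2821,0.4632,0.2301,0.2253,3,0.6931,0.9799,0.9549,0.8365,0.7282,0.5731,0.4269
DRIVE,0.2821,0.4632,0.2301,0.2253,4,0.6242,0.9767,0.9460,0.8005,0.6683,0.5027,0.4973
CHASE-DB1,0.1869,0.3961,0.1967,0.2670,2,0.8785,0.9911,0.9837,0.9355,0.8755,0.7788,0.2212
CHASE-DB1,0.1869,0.3961,0.1967,0.2670,3,0.8280,0.9872,0.9769,0.9076,0.8233,0.7002,0.2998
CHASE-DB1,0.1869,0.3961,0.1967,0.2670,4,0.7655,0.9866,0.9723,0.8761,0.7818,0.6427,0.3573
MC,0.0594,0.0367,0.0166,0.0016,2,0.9996,0.9997,0.9997,0.9996,0.9993,0.9986,0.0014
MC,0.0594,0.0367,0.0166,0.0016,3,0.9991,0.9996,0.9995,0.9991,0.9990,0.9980,0.0020
MC,0.0594,0.0367,0.0166,0.0016,4,0.9990,0.9995,0.9994,0.9990,0.9987,0.9975,0.0025
PH2,0.0248,0.0181,0.0049,0.0014,2,0.9985,0.9975,0.9984,0.9985,0.9965,0.9931,0.0069
PH2,0.0248,0.0181,0.0049,0.0014,3,0.9966,0.9974,0.9980,0.9966,0.9955,0.9910,0.0090
PH2,0.0248,0.0181,0.0049,0.0014,4,0.9958,0.9962,0.9971,0.9958,0.9936,0.9873,0.0127
ISIC-2016,0.0093,0.0106,0.0017,0.0128,2,0.9979,0.9994,0.9995,0.9979,0.9976,0.9953,0.0047
ISIC-2016,0.0093,0.0106,0.0017,0.0128,3,0.9968,0.9990,0.9992,0.9968,0.9962,0.9925,0.0075
ISIC-2016,0.0093,0.0106,0.0017,0.0128,4,0.9964,0.9990,0.9991,0.9964,0.9961,0.9922,0.0078
DRISHTI-OC,0.0090,0.0128,0.0072,0.0029,2,0.9943,1.0000,0.9990,0.9971,0.9961,0.9922,0.0078
DRISHTI-OC,0.0090,0.0128,0.0072,0.0029,3,0.9943,0.9999,0.9998,0.9971,0.9950,0.9901,0.0099
DRISHTI-OC,0.0090,0.0128,0.0072,0.0029,4,0.9901,0.9999,0.9997,0.9950,0.9918,0.9838,0.0162
DRISHTI-OD,0.0117,0.0104,0.0045,0.0013,2,0.9957,1.0000,0.9998,0.9978,0.9972,0.9943,0.0057
DRISHTI-OD,0.0117,0.0104,0.0045,0.0013,3,0.9955,0.9999,0.9998,0.9977,0.9963,0.9925,0.0075
DRISHTI-OD,0.0117,0.0104,0.0045,0.0013,4,0.9924,0.9998,0.9996,0.9961,0.9939,0.9880,0.0120
PROMISE12,0.1104,0.0469,0.0175,0.0035,2,0.9623,0.9988,0.9978,0.9805,0.9654,0.9336,0.0664
PROMISE12,0.1104,0.0469,0.0175,0.0035,3,0.9453,0.9988,0.9969,0.9722,0.9568,0.9178,0.0822
PROMISE12,0.1104,0.0469,0.0175,0.0035,4,0.9398,0.9985,0.9963,0.9692,0.9499,0.9054,0.0946
BCSS,0.0282,0.0163,0.0018,0.0085,2,0.9950,0.9988,0.9977,0.9969,0.9963,0.9927,0.0073
BCSS,0.0282,0.0163,0.0018,0.0085,3,0.9944,0.9971,0.9966,0.9957,0.9946,0.9894,0.0106
BCSS,0.0282,0.0163,0.0018,0.0085,4,0.9914,0.9964,0.9953,0.9939,0.9924,0.9851,0.0149
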