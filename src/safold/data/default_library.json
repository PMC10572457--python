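{
 "format": "safold-prototype-library",
 "version": 1,
 "letters": "AYBCDGILEFHKNSTVWXMPQRZ",
 "templates": {
  "A": [
   [
    1.4798,
    0.9897,
    -3.0
   ],
   [
    -2.044,
    0.9897,
    -1.5
   ],
   [
    -1.4321,
    -2.4805,
    0.0
   ],
   [
    1.8792,
    -1.2753,
    1.5
   ],
   [
    0.1173,
    1.7764,
    3.0
   ]
  ],
  "Y": [
   [
    -6.92,
    -0.6284,
    0.0
   ],
   [
    -3.46,
    0.9427,
    0.0
   ],
   [
    -0.0,
    -0.6284,
    0.0
   ],
   [
    3.46,
    0.9427,
    0.0
   ],
   [
    6.92,
    -0.6284,
    0.0
   ]
  ],
  "B": [
   [
    1.7604,
    4.787,
    0.0
   ],
   [
    -1.6968,
    3.2097,
    0.0
   ],
   [
    -2.7139,
    -0.4517,
    0.0
   ],
   [
    -0.5657,
    -3.5862,
    0.0
   ],
   [
    3.216,
    -3.9587,
    0.0
   ]
  ],
  "C": [
   [
    -3.9863,
    4.4987,
    2.535
   ],
   [
    -2.8729,
    1.2304,
    0.948
   ],
   [
    -0.3592,
    -1.6193,
    0.9756
   ],
   [
    2.6213,
    -3.0172,
    -0.9224
   ],
   [
    4.5972,
    -1.0926,
    -3.5362
   ]
  ],
  "D": [
   [
    4.9998,
    -4.1283,
    -2.2133
   ],
   [
    1.957,
    -1.6671,
    -1.4626
   ],
   [
    1.1286,
    0.9069,
    1.2407
   ],
   [
    -2.1985,
    1.8188,
    1.5546
   ],
   [
    -5.8869,
    3.0696,
    0.8807
   ]
  ],
  "G": [
   [
    -5.161,
    -0.4,
    2.6286
   ],
   [
    -1.4867,
    -0.0281,
    3.5236
   ],
   [
    1.0968,
    -1.4376,
    1.1197
   ],
   [
    1.6916,
    0.238,
    -2.2387
   ],
   [
    3.8594,
    1.6277,
    -5.0332
   ]
  ],
  "I": [
   [
    -3.5288,
    -0.7651,
    -0.849
   ],
   [
    -1.5409,
    -0.2608,
    1.8729
   ],
   [
    1.441,
    1.4454,
    3.3061
   ],
   [
    2.0228,
    0.2341,
    -0.359
   ],
   [
    1.6059,
    -0.6535,
    -3.971
   ]
  ],
  "L": [
   [
    -0.3929,
    -6.6778,
    -1.1803
   ],
   [
    -0.1651,
    -3.4778,
    0.8563
   ],
   [
    0.1966,
    0.3006,
    1.037
   ],
   [
    0.0176,
    3.2886,
    -1.3038
   ],
   [
    0.3438,
    6.5664,
    0.5908
   ]
  ],
  "E": [
   [
    5.573,
    -0.8838,
    -1.2749
   ],
   [
    2.1034,
    -2.382,
    -1.6717
   ],
   [
    -1.2533,
    -1.52,
    -0.113
   ],
   [
    -3.8982,
    0.6219,
    1.5772
   ],
   [
    -2.5249,
    4.1638,
    1.4823
   ]
  ],
  "F": [
   [
    -1.0132,
    4.7414,
    0.8685
   ],
   [
    0.3444,
    1.8694,
    2.9539
   ],
   [
    2.3272,
    0.4308,
    0.0488
   ],
   [
    0.076,
    -1.8512,
    -1.9919
   ],
   [
    -1.7344,
    -5.1904,
    -1.8794
   ]
  ],
  "H": [
   [
    -1.1741,
    -1.5879,
    5.5332
   ],
   [
    1.5902,
    -1.5129,
    3.1423
   ],
   [
    0.7504,
    0.7459,
    0.1075
   ],
   [
    0.0104,
    -0.4122,
    -3.2802
   ],
   [
    -1.1769,
    2.7671,
    -5.5028
   ]
  ],
  "K": [
   [
    -3.9104,
    -0.5985,
    1.3086
   ],
   [
    -2.7947,
    -2.0016,
    -2.2799
   ],
   [
    0.664,
    -1.5424,
    -1.8314
   ],
   [
    1.6887,
    0.6259,
    0.9726
   ],
   [
    4.3524,
    3.5166,
    1.8301
   ]
  ],
  "N": [
   [
    3.329,
    0.4843,
    4.0335
   ],
   [
    3.3494,
    1.3841,
    0.1395
   ],
   [
    0.5831,
    -1.0106,
    -0.1674
   ],
   [
    -2.9113,
    -1.8143,
    -0.9614
   ],
   [
    -4.3503,
    0.9565,
    -3.0443
   ]
  ],
  "S": [
   [
    -3.7641,
    2.1469,
    -0.5418
   ],
   [
    -1.2821,
    -0.3567,
    0.8766
   ],
   [
    0.7967,
    -2.8404,
    -1.1107
   ],
   [
    2.0393,
    -0.7405,
    1.8024
   ],
   [
    2.2102,
    1.7907,
    -1.0266
   ]
  ],
  "T": [
   [
    0.0416,
    5.9654,
    -1.5682
   ],
   [
    -0.1055,
    2.6474,
    -0.6504
   ],
   [
    0.0566,
    -1.4575,
    -0.7158
   ],
   [
    1.2413,
    -4.5656,
    0.4619
   ],
   [
    -1.234,
    -2.5897,
    2.4724
   ]
  ],
  "V": [
   [
    -3.4469,
    -2.7569,
    2.5086
   ],
   [
    -0.6066,
    -0.2069,
    3.5304
   ],
   [
    2.1577,
    -0.1319,
    1.1395
   ],
   [
    1.3179,
    2.1269,
    -1.8954
   ],
   [
    0.5779,
    0.9688,
    -5.2831
   ]
  ],
  "W": [
   [
    -1.8148,
    2.1438,
    -0.4025
   ],
   [
    -1.8437,
    3.0207,
    3.2949
   ],
   [
    -0.4785,
    -0.2531,
    1.9316
   ],
   [
    1.6,
    -2.1931,
    -0.5895
   ],
   [
    2.537,
    -2.7183,
    -4.2345
   ]
  ],
  "X": [
   [
    -0.9715,
    4.602,
    3.3854
   ],
   [
    -1.8419,
    1.8215,
    0.9459
   ],
   [
    -0.3016,
    -1.5662,
    0.177
   ],
   [
    1.996,
    -4.104,
    -1.4725
   ],
   [
    1.119,
    -0.7533,
    -3.0358
   ]
  ],
  "M": [
   [
    -3.305,
    -1.8372,
    -2.433
   ],
   [
    -0.7326,
    0.5987,
    -3.8074
   ],
   [
    -0.7593,
    -0.18,
    -0.0881
   ],
   [
    2.5075,
    -0.613,
    1.8042
   ],
   [
    2.2893,
    2.0314,
    4.5244
   ]
  ],
  "P": [
   [
    -0.2929,
    1.683,
    4.4297
   ],
   [
    -0.4873,
    2.6485,
    0.84
   ],
   [
    1.281,
    0.3719,
    -0.9285
   ],
   [
    1.1487,
    -3.3347,
    -0.9777
   ],
   [
    -1.6495,
    -1.3687,
    -3.3636
   ]
  ],
  "Q": [
   [
    0.281,
    2.3999,
    3.6276
   ],
   [
    -1.1741,
    0.0543,
    1.2866
   ],
   [
    2.2544,
    -0.3477,
    1.0725
   ],
   [
    0.6185,
    0.0198,
    -2.1145
   ],
   [
    -1.9798,
    -2.1262,
    -3.8722
   ]
  ],
  "R": [
   [
    -0.2997,
    1.3642,
    3.317
   ],
   [
    0.6239,
    -0.6695,
    -0.0832
   ],
   [
    -1.1221,
    -2.2908,
    -2.757
   ],
   [
    -1.4103,
    0.5711,
    -0.6414
   ],
   [
    2.2082,
    1.0249,
    0.1646
   ]
  ],
  "Z": [
   [
    -3.1422,
    -0.4996,
    0.675
   ],
   [
    -1.0634,
    -2.9833,
    -1.3123
   ],
   [
    0.1792,
    -0.8834,
    1.6008
   ],
   [
    0.35,
    1.6479,
    -1.2282
   ],
   [
    3.6765,
    2.7185,
    0.2647
   ]
  ]
 },
 "frequencies": {
  "A": 0.20959595959595959,
  "Y": 0.1734848484848485,
  "B": 0.14166666666666666,
  "C": 0.04242424242424243,
  "D": 0.04191919191919192,
  "G": 0.036616161616161616,
  "I": 0.03383838383838384,
  "L": 0.03308080808080808,
  "E": 0.026515151515151516,
  "F": 0.026262626262626262,
  "H": 0.025505050505050506,
  "K": 0.024242424242424242,
  "N": 0.022727272727272728,
  "S": 0.02070707070707071,
  "T": 0.020454545454545454,
  "V": 0.020202020202020204,
  "W": 0.019444444444444445,
  "X": 0.01919191919191919,
  "M": 0.015404040404040404,
  "P": 0.013383838383838383,
  "Q": 0.012626262626262626,
  "R": 0.010606060606060607,
  "Z": 0.010101010101010102
 }
}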