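{
 "version": 1,
 "units": "mm",
 "frame": "x anterior, y left, z superior; FH plane is z=0",
 "note": "Synthetic per-sex mean cranial landmark configurations, calibrated by least squares so each sex's template reproduces the packaged per-sex reference mean angles. Not derived from any real specimen.",
 "male": {
  "n|mid": [
   92.988,
   0.0,
   32.8053
  ],
  "b|mid": [
   19.9715,
   0.0,
   119.3403
  ],
  "g|mid": [
   95.3218,
   0.0,
   40.0858
  ],
  "m|mid": [
   85.1374,
   0.0,
   76.2528
  ],
  "ob|mid": [
   -44.999,
   0.0,
   102.6325
  ],
  "l|mid": [
   -66.3887,
   0.0,
   62.0151
  ],
  "op|mid": [
   -75.8401,
   0.0,
   16.8971
  ],
  "i|mid": [
   -71.5991,
   0.0,
   -1.4199
  ],
  "ba|mid": [
   -3.8227,
   0.0,
   -26.3201
  ],
  "o|mid": [
   -42.9473,
   0.0,
   -30.89
  ],
  "rhi|mid": [
   107.188,
   0.0,
   10.7137
  ],
  "ss|mid": [
   91.7876,
   0.0,
   -11.4741
  ],
  "pr|mid": [
   96.9492,
   0.0,
   -45.7064
  ],
  "mn|mid": [
   106.9443,
   0.0,
   13.1649
  ],
  "fmo|left": [
   76.7568,
   48.9766,
   19.446
  ],
  "fmo|right": [
   76.7568,
   -48.9766,
   19.446
  ],
  "ast|left": [
   -62.0583,
   54.8551,
   11.7148
  ],
  "ast|right": [
   -62.0583,
   -54.8551,
   11.7148
  ],
  "ms|left": [
   -3.3785,
   61.1161,
   -25.326
  ],
  "ms|right": [
   -3.3785,
   -61.1161,
   -25.326
  ],
  "mf|left": [
   88.5806,
   14.6666,
   18.1403
  ],
  "mf|right": [
   88.5806,
   -14.6666,
   18.1403
  ],
  "ek|left": [
   78.0863,
   44.7526,
   9.0788
  ],
  "ek|right": [
   78.0863,
   -44.7526,
   9.0788
  ],
  "so|left": [
   86.4293,
   30.6447,
   21.7172
  ],
  "so|right": [
   86.4293,
   -30.6447,
   21.7172
  ],
  "zo|left": [
   81.3715,
   28.3631,
   -9.044
  ],
  "zo|right": [
   81.3715,
   -28.3631,
   -9.044
  ],
  "nl|left": [
   92.2719,
   6.6937,
   -3.5399
  ],
  "nl|right": [
   92.2719,
   -6.6937,
   -3.5399
  ],
  "zm|left": [
   69.8315,
   42.6631,
   -26.7026
  ],
  "zm|right": [
   69.8315,
   -42.6631,
   -26.7026
  ],
  "nm|left": [
   92.4815,
   13.0815,
   1.8059
  ],
  "nm|right": [
   92.4815,
   -13.0815,
   1.8059
  ],
  "po|left": [
   0.0,
   61.0288,
   0.0
  ],
  "po|right": [
   0.0,
   -61.0288,
   0.0
  ],
  "or|left": [
   85.0,
   35.0,
   0.0
  ]
 },
 "female": {
  "n|mid": [
   91.4732,
   0.0,
   35.5148
  ],
  "b|mid": [
   22.7528,
   0.0,
   118.2879
  ],
  "g|mid": [
   92.7032,
   0.0,
   42.7802
  ],
  "m|mid": [
   86.5665,
   0.0,
   76.0377
  ],
  "ob|mid": [
   -44.08,
   0.0,
   102.3664
  ],
  "l|mid": [
   -65.5375,
   0.0,
   65.6337
  ],
  "op|mid": [
   -74.6887,
   0.0,
   16.2945
  ],
  "i|mid": [
   -71.087,
   0.0,
   4.741
  ],
  "ba|mid": [
   -4.9422,
   0.0,
   -28.6185
  ],
  "o|mid": [
   -42.6994,
   0.0,
   -34.0401
  ],
  "rhi|mid": [
   107.4278,
   0.0,
   10.1334
  ],
  "ss|mid": [
   90.3136,
   0.0,
   -17.2868
  ],
  "pr|mid": [
   95.7209,
   0.0,
   -49.7
  ],
  "mn|mid": [
   106.7945,
   0.0,
   13.7497
  ],
  "fmo|left": [
   78.1198,
   49.7838,
   21.2968
  ],
  "fmo|right": [
   78.1198,
   -49.7838,
   21.2968
  ],
  "ast|left": [
   -62.1946,
   54.825,
   11.431
  ],
  "ast|right": [
   -62.1946,
   -54.825,
   11.431
  ],
  "ms|left": [
   -4.1406,
   61.0262,
   -24.5345
  ],
  "ms|right": [
   -4.1406,
   -61.0262,
   -24.5345
  ],
  "mf|left": [
   88.826,
   16.6006,
   19.1939
  ],
  "mf|right": [
   88.826,
   -16.6006,
   19.1939
  ],
  "ek|left": [
   77.9505,
   45.1285,
   10.4825
  ],
  "ek|right": [
   77.9505,
   -45.1285,
   10.4825
  ],
  "so|left": [
   86.1772,
   30.4557,
   21.8022
  ],
  "so|right": [
   86.1772,
   -30.4557,
   21.8022
  ],
  "zo|left": [
   81.7069,
   28.7478,
   -9.1108
  ],
  "zo|right": [
   81.7069,
   -28.7478,
   -9.1108
  ],
  "nl|left": [
   92.2755,
   10.042,
   -6.2821
  ],
  "nl|right": [
   92.2755,
   -10.042,
   -6.2821
  ],
  "zm|left": [
   67.3482,
   41.4123,
   -26.4743
  ],
  "zm|right": [
   67.3482,
   -41.4123,
   -26.4743
  ],
  "nm|left": [
   93.3792,
   13.7582,
   2.1985
  ],
  "nm|right": [
   93.3792,
   -13.7582,
   2.1985
  ],
  "po|left": [
   0.0,
   61.1488,
   0.0
  ],
  "po|right": [
   0.0,
   -61.1488,
   0.0
  ],
  "or|left": [
   85.0,
   35.0,
   0.0
  ]
 }
}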