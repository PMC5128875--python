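schema: fibrilsim-wells-1
order: ACDEFGHIKLMNPQRSTVWY
depth:
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.05
  - 0.05
  - -0.15
  - -0.15
  - 0.05
  - 0.0
  - 0.3
  - 0.05
  - 0.3
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - 0.3
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.05
  - 0.05
  - -0.15
  - -0.15
  - 0.05
  - 0.0
  - 0.3
  - 0.05
  - 0.3
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - 0.3
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.05
  - 0.05
  - 0.3
  - 0.3
  - 0.05
  - 0.0
  - -0.15
  - 0.05
  - -0.15
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - -0.15
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.05
  - 0.05
  - 0.3
  - 0.3
  - 0.05
  - 0.0
  - -0.15
  - 0.05
  - -0.15
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - -0.15
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.05
  - 0.05
  - 0.1
  - 0.1
  - 0.05
  - 0.0
  - 0.1
  - 0.05
  - 0.1
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - 0.1
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.05
  - 0.05
  - 0.1
  - 0.1
  - 0.05
  - 0.0
  - 0.1
  - 0.05
  - 0.1
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - 0.1
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.05
  - 0.05
  - 0.3
  - 0.3
  - 0.05
  - 0.0
  - -0.15
  - 0.05
  - -0.15
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - -0.15
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.05
  - 0.05
  - 0.1
  - 0.1
  - 0.05
  - 0.0
  - 0.1
  - 0.05
  - 0.1
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - 0.1
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.05
  - 0.05
  - 0.1
  - 0.1
  - 0.05
  - 0.0
  - 0.1
  - 0.05
  - 0.1
  - 0.05
  - 0.05
  - 0.1
  - 0.05
  - 0.1
  - 0.1
  - 0.1
  - 0.1
  - 0.05
  - 0.05
  - 0.05
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
- - 0.2
  - 0.2
  - 0.05
  - 0.05
  - 0.2
  - 0.0
  - 0.05
  - 0.2
  - 0.05
  - 0.2
  - 0.2
  - 0.05
  - 0.2
  - 0.05
  - 0.05
  - 0.05
  - 0.05
  - 0.2
  - 0.2
  - 0.2
range:
- - 4.5577
  - 4.9945
  - 5.1315
  - 5.4937
  - 6.0196
  - 4.6039
  - 5.7515
  - 5.764
  - 5.8011
  - 5.764
  - 5.8254
  - 5.2565
  - 5.3875
  - 5.5934
  - 5.9978
  - 4.6953
  - 5.1315
  - 5.4641
  - 6.3294
  - 6.1044
- - 4.9945
  - 5.4313
  - 5.5683
  - 5.9306
  - 6.4564
  - 5.0407
  - 6.1883
  - 6.2008
  - 6.2379
  - 6.2008
  - 6.2622
  - 5.6933
  - 5.8243
  - 6.0302
  - 6.4346
  - 5.1321
  - 5.5683
  - 5.9009
  - 6.7662
  - 6.5412
- - 5.1315
  - 5.5683
  - 5.7053
  - 6.0675
  - 6.5934
  - 5.1777
  - 6.3253
  - 6.3378
  - 6.3749
  - 6.3378
  - 6.3992
  - 5.8303
  - 5.9613
  - 6.1672
  - 6.5716
  - 5.2691
  - 5.7053
  - 6.0379
  - 6.9032
  - 6.6782
- - 5.4937
  - 5.9306
  - 6.0675
  - 6.4298
  - 6.9556
  - 5.5399
  - 6.6875
  - 6.7
  - 6.7371
  - 6.7
  - 6.7614
  - 6.1925
  - 6.3236
  - 6.5294
  - 6.9338
  - 5.6314
  - 6.0675
  - 6.4002
  - 7.2654
  - 7.0404
- - 6.0196
  - 6.4564
  - 6.5934
  - 6.9556
  - 7.4815
  - 6.0657
  - 7.2133
  - 7.2259
  - 7.263
  - 7.2259
  - 7.2873
  - 6.7184
  - 6.8494
  - 7.0553
  - 7.4597
  - 6.1572
  - 6.5934
  - 6.926
  - 7.7913
  - 7.5663
- - 4.6039
  - 5.0407
  - 5.1777
  - 5.5399
  - 6.0657
  - 4.65
  - 5.7976
  - 5.8101
  - 5.8472
  - 5.8101
  - 5.8715
  - 5.3026
  - 5.4337
  - 5.6395
  - 6.0439
  - 4.7415
  - 5.1777
  - 5.5103
  - 6.3755
  - 6.1505
- - 5.7515
  - 6.1883
  - 6.3253
  - 6.6875
  - 7.2133
  - 5.7976
  - 6.9452
  - 6.9577
  - 6.9948
  - 6.9577
  - 7.0191
  - 6.4502
  - 6.5813
  - 6.7871
  - 7.1915
  - 5.8891
  - 6.3253
  - 6.6579
  - 7.5231
  - 7.2981
- - 5.764
  - 6.2008
  - 6.3378
  - 6.7
  - 7.2259
  - 5.8101
  - 6.9577
  - 6.9703
  - 7.0074
  - 6.9703
  - 7.0316
  - 6.4627
  - 6.5938
  - 6.7997
  - 7.2041
  - 5.9016
  - 6.3378
  - 6.6704
  - 7.5356
  - 7.3107
- - 5.8011
  - 6.2379
  - 6.3749
  - 6.7371
  - 7.263
  - 5.8472
  - 6.9948
  - 7.0074
  - 7.0444
  - 7.0074
  - 7.0687
  - 6.4998
  - 6.6309
  - 6.8367
  - 7.2411
  - 5.9387
  - 6.3749
  - 6.7075
  - 7.5727
  - 7.3478
- - 5.764
  - 6.2008
  - 6.3378
  - 6.7
  - 7.2259
  - 5.8101
  - 6.9577
  - 6.9703
  - 7.0074
  - 6.9703
  - 7.0316
  - 6.4627
  - 6.5938
  - 6.7997
  - 7.2041
  - 5.9016
  - 6.3378
  - 6.6704
  - 7.5356
  - 7.3107
- - 5.8254
  - 6.2622
  - 6.3992
  - 6.7614
  - 7.2873
  - 5.8715
  - 7.0191
  - 7.0316
  - 7.0687
  - 7.0316
  - 7.093
  - 6.5241
  - 6.6552
  - 6.861
  - 7.2654
  - 5.963
  - 6.3992
  - 6.7318
  - 7.597
  - 7.3721
- - 5.2565
  - 5.6933
  - 5.8303
  - 6.1925
  - 6.7184
  - 5.3026
  - 6.4502
  - 6.4627
  - 6.4998
  - 6.4627
  - 6.5241
  - 5.9552
  - 6.0863
  - 6.2921
  - 6.6965
  - 5.3941
  - 5.8303
  - 6.1629
  - 7.0281
  - 6.8032
- - 5.3875
  - 5.8243
  - 5.9613
  - 6.3236
  - 6.8494
  - 5.4337
  - 6.5813
  - 6.5938
  - 6.6309
  - 6.5938
  - 6.6552
  - 6.0863
  - 6.2173
  - 6.4232
  - 6.8276
  - 5.5251
  - 5.9613
  - 6.2939
  - 7.1592
  - 6.9342
- - 5.5934
  - 6.0302
  - 6.1672
  - 6.5294
  - 7.0553
  - 5.6395
  - 6.7871
  - 6.7997
  - 6.8367
  - 6.7997
  - 6.861
  - 6.2921
  - 6.4232
  - 6.6291
  - 7.0335
  - 5.731
  - 6.1672
  - 6.4998
  - 7.365
  - 7.1401
- - 5.9978
  - 6.4346
  - 6.5716
  - 6.9338
  - 7.4597
  - 6.0439
  - 7.1915
  - 7.2041
  - 7.2411
  - 7.2041
  - 7.2654
  - 6.6965
  - 6.8276
  - 7.0335
  - 7.4379
  - 6.1354
  - 6.5716
  - 6.9042
  - 7.7694
  - 7.5445
- - 4.6953
  - 5.1321
  - 5.2691
  - 5.6314
  - 6.1572
  - 4.7415
  - 5.8891
  - 5.9016
  - 5.9387
  - 5.9016
  - 5.963
  - 5.3941
  - 5.5251
  - 5.731
  - 6.1354
  - 4.8329
  - 5.2691
  - 5.6017
  - 6.467
  - 6.242
- - 5.1315
  - 5.5683
  - 5.7053
  - 6.0675
  - 6.5934
  - 5.1777
  - 6.3253
  - 6.3378
  - 6.3749
  - 6.3378
  - 6.3992
  - 5.8303
  - 5.9613
  - 6.1672
  - 6.5716
  - 5.2691
  - 5.7053
  - 6.0379
  - 6.9032
  - 6.6782
- - 5.4641
  - 5.9009
  - 6.0379
  - 6.4002
  - 6.926
  - 5.5103
  - 6.6579
  - 6.6704
  - 6.7075
  - 6.6704
  - 6.7318
  - 6.1629
  - 6.2939
  - 6.4998
  - 6.9042
  - 5.6017
  - 6.0379
  - 6.3705
  - 7.2358
  - 7.0108
- - 6.3294
  - 6.7662
  - 6.9032
  - 7.2654
  - 7.7913
  - 6.3755
  - 7.5231
  - 7.5356
  - 7.5727
  - 7.5356
  - 7.597
  - 7.0281
  - 7.1592
  - 7.365
  - 7.7694
  - 6.467
  - 6.9032
  - 7.2358
  - 8.101
  - 7.8761
- - 6.1044
  - 6.5412
  - 6.6782
  - 7.0404
  - 7.5663
  - 6.1505
  - 7.2981
  - 7.3107
  - 7.3478
  - 7.3107
  - 7.3721
  - 6.8032
  - 6.9342
  - 7.1401
  - 7.5445
  - 6.242
  - 6.6782
  - 7.0108
  - 7.8761
  - 7.6511
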