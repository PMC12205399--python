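sex,age,rate
male,0,0.00598
male,1,0.00037
male,2,0.000237486
male,3,0.000178967
male,4,0.000152091
male,5,0.00014
male,6,0.000132895
male,7,0.000127335
male,8,0.000123311
male,9,0.000120845
male,10,0.00012
male,11,0.000138179
male,12,0.000195903
male,13,0.000305991
male,14,0.000471172
male,15,0.00064
male,16,0.000777624
male,17,0.000923214
male,18,0.00107141
male,19,0.00121593
male,20,0.00135
male,21,0.00147359
male,22,0.00159049
male,23,0.00170023
male,24,0.00180307
male,25,0.0019
male,26,0.00198801
male,27,0.00206647
male,28,0.00214138
male,29,0.00221982
male,30,0.00231
male,31,0.00241699
male,32,0.00253732
male,33,0.00266667
male,34,0.00279971
male,35,0.00293
male,36,0.00305198
male,37,0.00316919
male,38,0.0032888
male,39,0.00341917
male,40,0.00357
male,41,0.00374883
male,42,0.00395476
male,43,0.00418569
male,44,0.00443873
male,45,0.00471
male,46,0.00500171
male,47,0.00532088
male,48,0.00567006
male,49,0.00605207
male,50,0.00647
male,51,0.00693475
male,52,0.00745331
male,53,0.00802175
male,54,0.00863374
male,55,0.00928
male,56,0.009961
male,57,0.0106871
male,58,0.0114616
male,59,0.0122879
male,60,0.01317
male,61,0.0141035
male,62,0.0150899
male,63,0.0161446
male,64,0.0172868
male,65,0.01854
male,66,0.0199099
male,67,0.0213978
male,68,0.023028
male,69,0.0248301
male,70,0.02684
male,71,0.0291347
male,72,0.0317516
male,73,0.0346614
male,74,0.0378133
male,75,0.04113
male,76,0.0445261
male,77,0.0480515
male,78,0.0518359
male,79,0.056051
male,80,0.06092
male,81,0.0666885
male,82,0.0734218
male,83,0.0810956
male,84,0.0896361
male,85,0.0989
male,86,0.109036
male,87,0.120318
male,88,0.132686
male,89,0.146017
male,90,0.16011
male,91,0.17498
male,92,0.190818
male,93,0.207604
male,94,0.225303
male,95,0.24386
male,96,0.263308
male,97,0.283704
male,98,0.304999
male,99,0.327126
male,100,0.35
female,0,0.00499
female,1,0.00031
female,2,0.000192866
female,3,0.000141572
female,4,0.000118686
female,5,0.00011
female,6,0.000106388
female,7,0.000103598
female,8,0.000101607
female,9,0.000100405
female,10,0.0001
female,11,0.000109621
female,12,0.000137828
female,13,0.000185341
female,14,0.000248561
female,15,0.00031
female,16,0.00036202
female,17,0.000417163
female,18,0.000473586
female,19,0.000528851
female,20,0.00058
female,21,0.000625568
female,22,0.00066711
female,23,0.000706508
female,24,0.000746369
female,25,0.00079
female,26,0.000837379
female,27,0.000886289
female,28,0.000937428
female,29,0.000991652
female,30,0.00105
female,31,0.00111356
female,32,0.00118223
female,33,0.00125525
female,34,0.00133161
female,35,0.00141
female,36,0.00148863
female,37,0.00156814
female,38,0.00165105
female,39,0.00174043
female,40,0.00184
female,41,0.00195159
female,42,0.00207463
female,43,0.00220986
female,44,0.00235806
female,45,0.00252
female,46,0.0026998
female,47,0.00290049
female,48,0.00312074
female,49,0.00335833
female,50,0.00361
female,51,0.00387575
female,52,0.00415955
female,53,0.00446332
female,54,0.00478928
female,55,0.00514
female,56,0.00551784
female,57,0.00592429
female,58,0.00636084
female,59,0.00682894
female,60,0.00733
female,61,0.00786119
female,62,0.00842442
female,63,0.00902975
female,64,0.00968975
female,65,0.01042
female,66,0.0112291
female,67,0.0121199
female,68,0.0131033
female,69,0.0141918
female,70,0.0154
female,71,0.0167539
female,72,0.0182743
female,73,0.0199681
female,74,0.0218397
female,75,0.02389
female,76,0.0261014
female,77,0.0284993
female,78,0.0311605
female,79,0.0341864
female,80,0.03771
female,81,0.0419316
female,82,0.0469617
female,83,0.0528093
female,84,0.059441
female,85,0.06676
female,86,0.074903
female,87,0.0841277
female,88,0.0944249
female,89,0.105729
female,90,0.1179
female,91,0.130963
female,92,0.145102
female,93,0.160346
female,94,0.17671
female,95,0.1942
female,96,0.212878
female,97,0.232811
female,98,0.253994
female,99,0.276405
female,100,0.3
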