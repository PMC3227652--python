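provenance:
  note: 'found by rejection sampling the default (oscillatory: oscillation-biased)
    ranges; labels confirmed with the fixed-step RK4 oracle at freeze time'
  search_seed: 20110184
fixtures:
  sustained:
    parameters:
      k1: 0.0005198242873263864
      k2: 0.0005316454148206254
      k3: 0.0010694423581302025
      k4: 0.027232498786693475
      k5: 0.14165362701783749
      k6: 0.00027828706323275085
      k7: 0.008522636690110625
      k8: 0.01890997000346251
      k9: 0.028680183291294334
      k10: 0.003430392470561108
      k11: 0.061472902182825535
      k12: 0.0004501785585330482
      k13: 0.012674801182554641
      k14: 4.982226930117028e-06
      k15: 0.013000006149832623
      k16: 0.031043349898565407
      k17: 0.0008234995063964985
      k18: 0.003027494806140417
      k19: 0.00017633158054259615
      h: 2.0
    expected_label: sustained
    oracle_label: sustained
    Opeak_pM: 285.2701684508112
    F: 4067.284874909208
    D: 0.004295086376733147
    T: 4.507772849807513e-09
  transient:
    parameters:
      k1: 1.0207680288256887e-06
      k2: 3.94151002839439e-05
      k3: 0.004705192306381514
      k4: 3.386670392770999e-05
      k5: 0.03891923639445375
      k6: 1.9585356271476638e-05
      k7: 0.0017562106005546546
      k8: 0.026375083601010256
      k9: 0.010821830827587933
      k10: 0.0003590359815315213
      k11: 0.015240611397449507
      k12: 0.1792469910452466
      k13: 0.009534901730850595
      k14: 0.00035424188554096357
      k15: 0.038109798292834965
      k16: 0.0018246137953522382
      k17: 1.708380387378783e-05
      k18: 0.04593827364889582
      k19: 0.00020645774525063354
      h: 2.0
    expected_label: transient
    oracle_label: transient
    Opeak_pM: 27.497307539465577
    F: 240577500.68431213
    D: 0.010675162176417743
    T: 6.4355654451672385e-12
  unresponsive:
    parameters:
      k1: 2.232041265117985e-05
      k2: 3.130673584451257e-05
      k3: 0.00013551400858727118
      k4: 0.0010669571086314126
      k5: 0.052698398015884565
      k6: 0.0018515302443097169
      k7: 0.0037132294656950764
      k8: 0.05552238526770152
      k9: 0.0002687137127955001
      k10: 0.002523588532302394
      k11: 0.015874522811400605
      k12: 0.018043219970046955
      k13: 0.04058862864762488
      k14: 0.020273585056760704
      k15: 7.780159398451526
      k16: 0.0007638894048640543
      k17: 0.0022717508482167103
      k18: 0.0022987821208432777
      k19: 6.150643463000383e-05
      h: 2.0
    expected_label: unresponsive
    oracle_label: unresponsive
    Opeak_pM: 6.727945420747043
    F: 1220.1837034210037
    D: 0.01417603013015798
    T: 1.0673620025251314e-10
  oscillatory:
    parameters:
      k1: 0.0013689709485086386
      k2: 8.890924654376998e-05
      k3: 0.006365461370357785
      k4: 8.72772671211164e-05
      k5: 0.3239561465423382
      k6: 0.0002013134560053903
      k7: 0.00042000755681656786
      k8: 0.00023862168810890707
      k9: 0.027611313484615478
      k10: 0.0003355528291086098
      k11: 0.014278004912698017
      k12: 0.006111193710528029
      k13: 0.01908560415599746
      k14: 0.008159249492019257
      k15: 2.555077359271952
      k16: 0.0031900597381377266
      k17: 0.0008237430290314522
      k18: 0.0015628622124431225
      k19: 0.0012905968826194057
      h: 2.0
    expected_label: dampened_oscillatory
    oracle_label: dampened_oscillatory
    Opeak_pM: 142.82601754570277
    F: 7554.363979325364
    D: 0.00019378602219855996
    T: 3.3914169000784458e-09
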