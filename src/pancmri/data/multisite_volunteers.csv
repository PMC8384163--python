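subject,site,measure,value
V1,Nashville,volume,81.297
V1,Austin,volume,59.616
V1,Denver,volume,60.768
V1,Chicago,volume,67.914
V2,Nashville,volume,73.602
V2,Austin,volume,74.214
V2,Denver,volume,87.93
V2,Chicago,volume,73.134
V3,Nashville,volume,112.75
V3,Austin,volume,122.29
V3,Denver,volume,127.75
V3,Chicago,volume,112.9
V4,Nashville,volume,57.177
V4,Austin,volume,60.381
V4,Denver,volume,63.351
V4,Chicago,volume,70.839
V5,Nashville,volume,96.57
V5,Austin,volume,116.41
V5,Denver,volume,103.18
V5,Chicago,volume,100.39
V1,Nashville,pvi,1.0862
V1,Austin,pvi,0.79655
V1,Denver,pvi,0.77619
V1,Chicago,pvi,0.90742
V2,Nashville,pvi,1.081765
V2,Austin,pvi,1.09808
V2,Denver,pvi,1.294076
V2,Chicago,pvi,1.07488
V3,Nashville,pvi,1.1893
V3,Austin,pvi,1.29617
V3,Denver,pvi,1.30389
V3,Chicago,pvi,1.1852
V4,Nashville,pvi,0.7781
V4,Austin,pvi,0.80677
V4,Denver,pvi,0.84645
V4,Chicago,pvi,0.97
V5,Nashville,pvi,0.9721
V5,Austin,pvi,1.19367
V5,Denver,pvi,1.04345
V5,Chicago,pvi,1.0294
V1,Nashville,mtr,0.37469
V1,Austin,mtr,0.44421
V1,Denver,mtr,0.44516
V1,Chicago,mtr,0.24861
V2,Nashville,mtr,0.41664
V2,Austin,mtr,0.30807
V2,Denver,mtr,0.31042
V2,Chicago,mtr,0.055648
V3,Nashville,mtr,0.40765
V3,Austin,mtr,0.28954
V3,Denver,mtr,0.34684
V3,Chicago,mtr,
V4,Nashville,mtr,0.249
V4,Austin,mtr,0.32639
V4,Denver,mtr,0.3998
V4,Chicago,mtr,0.085408
V5,Nashville,mtr,0.39885
V5,Austin,mtr,0.40804
V5,Denver,mtr,0.39628
V5,Chicago,mtr,0.089641
V1,Nashville,adc,0.0011888
V1,Austin,adc,0.0010299
V1,Denver,adc,0.0011715
V1,Chicago,adc,0.0012272
V2,Nashville,adc,0.0012611
V2,Austin,adc,0.0012671
V2,Denver,adc,0.0014773
V2,Chicago,adc,0.0014198
V3,Nashville,adc,0.0012716
V3,Austin,adc,0.001267
V3,Denver,adc,0.0011184
V3,Chicago,adc,0.0010943
V4,Nashville,adc,0.0013227
V4,Austin,adc,0.0014217
V4,Denver,adc,0.0011917
V4,Chicago,adc,0.0011398
V5,Nashville,adc,0.0010012
V5,Austin,adc,0.00094109
V5,Denver,adc,0.0008776
V5,Chicago,adc,0.0010638
V1,Nashville,t1,958.61
V1,Austin,t1,890.77
V1,Denver,t1,866.19
V1,Chicago,t1,1043.3
V2,Nashville,t1,1108.1
V2,Austin,t1,1236.4
V2,Denver,t1,1311.6
V2,Chicago,t1,1055.5
V3,Nashville,t1,1168.1
V3,Austin,t1,874.06
V3,Denver,t1,818.81
V3,Chicago,t1,989.93
V4,Nashville,t1,901.82
V4,Austin,t1,897.35
V4,Denver,t1,868.17
V4,Chicago,t1,918.05
V5,Nashville,t1,676.91
V5,Austin,t1,839.37
V5,Denver,t1,830.25
V5,Chicago,t1,707.06
V1,Nashville,panc_fat_fraction,0.1472
V1,Austin,panc_fat_fraction,0.13584
V1,Denver,panc_fat_fraction,
V1,Chicago,panc_fat_fraction,0.18757
V2,Nashville,panc_fat_fraction,0.020894
V2,Austin,panc_fat_fraction,
V2,Denver,panc_fat_fraction,
V2,Chicago,panc_fat_fraction,0.060248
V3,Nashville,panc_fat_fraction,0.13
V3,Austin,panc_fat_fraction,0.13369
V3,Denver,panc_fat_fraction,
V3,Chicago,panc_fat_fraction,0.12877
V4,Nashville,panc_fat_fraction,0.077119
V4,Austin,panc_fat_fraction,0.078579
V4,Denver,panc_fat_fraction,
V4,Chicago,panc_fat_fraction,0.13843
V5,Nashville,panc_fat_fraction,0.23798
V5,Austin,panc_fat_fraction,0.2386
V5,Denver,panc_fat_fraction,
V5,Chicago,panc_fat_fraction,0.20345
V1,Nashville,hep_fat_fraction,0.0422
V1,Austin,hep_fat_fraction,0.0296
V1,Denver,hep_fat_fraction,
V1,Chicago,hep_fat_fraction,0.0312
V2,Nashville,hep_fat_fraction,0.0465
V2,Austin,hep_fat_fraction,
V2,Denver,hep_fat_fraction,
V2,Chicago,hep_fat_fraction,0.024
V3,Nashville,hep_fat_fraction,0.0394
V3,Austin,hep_fat_fraction,0.0293
V3,Denver,hep_fat_fraction,
V3,Chicago,hep_fat_fraction,0.0185
V4,Nashville,hep_fat_fraction,0.0298
V4,Austin,hep_fat_fraction,0.0163
V4,Denver,hep_fat_fraction,
V4,Chicago,hep_fat_fraction,0.0269
V5,Nashville,hep_fat_fraction,0.1381
V5,Austin,hep_fat_fraction,0.1111
V5,Denver,hep_fat_fraction,
V5,Chicago,hep_fat_fraction,0.1686
V1,Nashville,surface_to_volume,0.1017
V1,Austin,surface_to_volume,0.10107
V1,Denver,surface_to_volume,0.10482
V1,Chicago,surface_to_volume,0.095063
V2,Nashville,surface_to_volume,0.1118
V2,Austin,surface_to_volume,0.10107
V2,Denver,surface_to_volume,0.10595
V2,Chicago,surface_to_volume,0.11043
V3,Nashville,surface_to_volume,0.087008
V3,Austin,surface_to_volume,0.086092
V3,Denver,surface_to_volume,0.075841
V3,Chicago,surface_to_volume,0.095138
V4,Nashville,surface_to_volume,0.11663
V4,Austin,surface_to_volume,0.11427
V4,Denver,surface_to_volume,0.11303
V4,Chicago,surface_to_volume,0.11338
V5,Nashville,surface_to_volume,0.075479
V5,Austin,surface_to_volume,0.083718
V5,Denver,surface_to_volume,0.070601
V5,Chicago,surface_to_volume,0.081018
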