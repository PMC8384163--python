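subject,site,measure,value
phantom,Nashville,volume,90.8
phantom,Austin,volume,87.4
phantom,Denver,volume,91
phantom,Chicago,volume,91.2
phantom,Melbourne,volume,89.5
phantom,Nashville,mtr,0.383
phantom,Austin,mtr,0.378
phantom,Denver,mtr,0.384
phantom,Chicago,mtr,0.317
phantom,Melbourne,mtr,0.326
phantom,Nashville,adc,0.0014
phantom,Austin,adc,0.0014
phantom,Denver,adc,0.0013
phantom,Chicago,adc,0.0013
phantom,Melbourne,adc,0.0015
phantom,Nashville,t1_vial_1,468
phantom,Austin,t1_vial_1,500
phantom,Denver,t1_vial_1,494
phantom,Chicago,t1_vial_1,454
phantom,Melbourne,t1_vial_1,447
phantom,Nashville,t1_vial_2,948
phantom,Austin,t1_vial_2,1038
phantom,Denver,t1_vial_2,1020
phantom,Chicago,t1_vial_2,1141
phantom,Melbourne,t1_vial_2,897
phantom,Nashville,t1_vial_3,1284
phantom,Austin,t1_vial_3,1250
phantom,Denver,t1_vial_3,1256
phantom,Chicago,t1_vial_3,1375
phantom,Melbourne,t1_vial_3,1092
phantom,Nashville,t1_vial_4,1570
phantom,Austin,t1_vial_4,1550
phantom,Denver,t1_vial_4,1600
phantom,Chicago,t1_vial_4,1625
phantom,Melbourne,t1_vial_4,1354
phantom,Nashville,fat_fraction,96.7
phantom,Austin,fat_fraction,95.9
phantom,Denver,fat_fraction,
phantom,Chicago,fat_fraction,96.2
phantom,Melbourne,fat_fraction,95.6
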