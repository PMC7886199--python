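watershed,site,distance_upstream_m,reach_length_m,bankfull_width_m,aspect_deg,gradient_pct,elevation_m
West Fork Tectah,WFT1_lower,140,225,6.6,75,1.4,351.3
West Fork Tectah,WFT1_upper,535,175,6.0,90,2.2,359.2
West Fork Tectah,WFT2_lower,2750,205,4.7,350,2.9,409.0
West Fork Tectah,WFT2_upper,3320,195,3.7,15,3.2,429.2
West Fork Tectah,WFT3,3840,220,3.2,25,6.4,456.5
East Fork Tectah,EFT1_lower,450,195,5.3,310,3.9,363.5
East Fork Tectah,EFT1_upper,990,170,6.1,325,5.3,385.5
East Fork Tectah,EFT2,1850,225,4.6,345,3.8,421.3
Lost Man,LM1,1450,130,4.5,220,2.8,357.8
Lost Man,LM2,2300,140,4.1,275,3.1,368.8
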