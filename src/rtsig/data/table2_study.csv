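sample_id,cohort,diagnosis_label,initial_diagnosis,age_years,sex,location,outcome,followup_days
INI25,study,RT,RT,0.2,M,Soft-part,NA,NA
INI29,study,RT,RT,?,M,Kidney,NA,NA
INI44,study,RT,RT,7.3,M,Kidney,NA,NA
INI53,study,RT,RT,0.7,M,Periph. nerve,NA,NA
INI61,study,RT,RT,8,M,"Thx, pararachis",NED,1825
INI64,study,RT,RT,21,M,Forearm,DOD,300
INI105,study,RT,RT,33,F,Retro-periton.,DOD,66
INI116,study,RT,RT,3.4,M,Foot,NED,1370
INI120,study,RT,RT,18,F,Paraspinal/ORL,DOD,774
INI127,study,RT,ES,40,M,Groin,NED,790
INI135,study,RT,RT,22,M,Fro. meninges,NED,60
INI136,study,RT,RT,14,M,Brachial plexus,NED,1005
INI143,study,RT,RT,10,M,Kidney,NED,610
INI174,study,RT,MyoEC,27,M,"Soft-part, limb",DOD,172
INI176,study,RT,RT,28,F,"Soft-part, leg",NA,NA
INI185,study,RT,MyoEC,43,F,Vulva,NA,NA
INI20,study,SD-NRT,RT,6.7,M,Adrenal Gland,DOD,120
INI21,study,SD-NRT,RT,1.6,F,Kidney,DOD,179
INI37,study,ES,RT,25,F,Lung,DOD,51
INI38,study,SD-NRT,RT,0.8,M,Bladder,DOD,90
INI65,study,SD-NRT,eMPNST,54,F,Periph. nerve,DOD,93
INI86,study,SD-NRT,RT,6,M,Thorax,NED,13yrs
INI106,study,SD-NRT,RT,1.2,M,Soft-parts,NED,988
INI114,study,SD-NRT,RT,26,F,Thorax,DOD,387
INI115,study,SD-NRT,SD-NRT,26,F,Cavum,NED,855
INI117,study,UC,RT,16,M,Paraspinal,DOD,122
INI123,study,SD-NRT,ES,38,F,Not found,DOD,260
INI128,study,ES,ES,13,M,Leg,NED,422
INI129,study,SD-NRT,SD-NRT,53,F,Groin,NA,NA
INI130,study,ES,ES,9,F,Buttock,NED,810
INI131,study,SD-NRT,RT,31,M,Pleura,DOD,155
INI132,study,SD-NRT,AT/RT,39,M,Para. meninges,NED,239
INI133,study,ES,ES,10,M,Elbow,NED,684
INI134,study,ES,RT,34,M,Abdomen,DOD,7
INI152,study,SD-NRT,MPNST,30,F,Periph. nerve,DOD,45
INI175,study,ES,RT,14,F,Neck,DOD,910
INI182,study,SD-NRT,RT,51,M,Kidney,NED,-
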