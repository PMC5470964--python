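sample_id,cohort,diagnosis_label,age_years,sex,location,outcome,followup_days
INI18,training,RT,<2,NA,Kidney,NA,NA
INI19,training,RT,0.4,NA,Soft-parts,NA,NA
INI22,training,RT,4.5,NA,Soft-parts,NA,NA
INI23,training,RT,<2,NA,Kidney,NA,NA
INI24,training,RT,0.1,NA,Soft-parts,NA,NA
INI26,training,RT,0.5,NA,Soft-parts,NA,NA
INI39,training,RT,1,NA,Kidney,NA,NA
INI50,training,RT,0.1,NA,Soft-parts,NA,NA
INI59,training,RT,0.5,NA,Soft-parts,NA,NA
INI56,training,RT,0.1,NA,Soft-parts,NA,NA
INI90,training,RT,1.8,NA,Bladder,NA,NA
INI91,training,RT,2.1,NA,Brachial Plexus,NA,NA
INI93,training,RT,2,NA,Kidney,NA,NA
INI97,training,RT,1.9,NA,Kidney,NA,NA
INI109,training,RT,1.7,NA,Soft-parts,NA,NA
INI110,training,RT,2.5,NA,Soft-parts,NA,NA
INI85,training,RMC,38,NA,Kidney,NA,NA
INI95,training,RMC,29,NA,Kidney,NA,NA
INI111,training,RMC,8,NA,Kidney,NA,NA
INI137,training,RMC,16,NA,Kidney,NA,NA
INI141,training,RMC,33,NA,Kidney,NA,NA
INI138,training,UC,2.2,NA,Clivus,NA,NA
INI142,training,UC,2,NA,Clivus,NA,NA
INI144,training,UC,3,NA,Clivus,NA,NA
PT25,training,ES,48,NA,Pelvis,NA,NA
PT26,training,ES,13.6,NA,Groin,NA,NA
INI66,training,ES,23,NA,Thigh,NA,NA
INI121,training,ES,29,NA,Thigh,NA,NA
INI122,training,ES,25.8,NA,Forearm,NA,NA
INI124,training,ES,17,NA,Perineum,NA,NA
INI125,training,ES,18,NA,NA,NA,NA
INI126,training,ES,16.8,NA,Arm,NA,NA
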