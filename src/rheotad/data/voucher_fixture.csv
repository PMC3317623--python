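species_label,candidate_code,evidence,field_number,zsm_number,accession,locality,ref_locality,same_region,gosner_stage,BL,TL,ltrf,MP,SMP,best_identity,best_reference,ref_species,ref_role,ref_status,geographic_parsimony,has_dorsal_gap,has_upper_jaw_sheath,oral_disc_margin,lower_sheath_shape,cluster,guild,sympatric_with,confirmed_candidate
Boophis englaenderi,,,FGZC 2244,ZSM 623/2008,HM769921,Marojejy National Park,Marojejy National Park,True,36,11.8,25.4,6(3–6)/3(1),128,33,99.5,FJ559124,Boophis englaenderi,adult_reference,described_species,False,True,True,continuous_with_snout,V,1,clasping,Boophis englaenderi [Ca23],False
Boophis englaenderi,23,Vieites et al. 2009,FGZC 2957,ZSM 1632/2007,JQ518193,Marojejy National Park,Ilampy,False,30,10.5,29.5,7(3–7)/3,175,94,94.0,AY848474,Boophis englaenderi,adult_reference,described_species,False,True,True,continuous_with_snout,,1,clasping,Boophis englaenderi,True
Boophis andohahela,,,T 428,ZSM 998/2007,GU974449,Ranomafana National Park,Ranomafana National Park,True,26,11.8,25.4,6(3–6)/3,,,100.0,AY848456,Boophis andohahela,adult_reference,described_species,False,True,True,continuous_with_snout,,1,clasping,,False
Boophis ankaratra,,,ZCMV 4917,ZSM 876/2007,GU974476,Ranomafana National Park,Mandraka,True,28,11.3,25.5,8(5–8)/3,148,190,100.0,AJ315909,Boophis ankaratra,adult_reference,described_species,False,True,True,free,U,2,adherent,Boophis schuboeae,False
Boophis schuboeae,,,FGMV 2002-1800,ZSM 978/2004,DQ068394,Ranomafana National Park,Ranomafana National Park,True,36,12.1,25.5,8(5–8)/3,,,100.0,AJ315912,Boophis schuboeae,adult_reference,described_species,False,True,True,free,U,2,adherent,Boophis ankaratra,False
Boophis albipunctatus,,,ZCMV 4946,ZSM 82/2008,GU974374,Ambohitsara-Tsitolaka,Manantantely,True,25,7.5,15.5,7(5–7)/3,,,99.0,AY848446,Boophis albipunctatus,adult_reference,described_species,False,True,True,free,U,2,adherent,,False
Boophis sibilans,,,FGZC 2956,ZSM 1631/2007,JQ518194,Marojejy National Park,Andasibe,True,29,11.0,26.0,7(5–7)/3,,,99.4,AY341718,Boophis sibilans,adult_reference,described_species,False,True,True,free,V,2,adherent,,False
Boophis luciae,,,ZCMV 5146,ZSM 730/2007,GU975069,Ranomafana National Park,Ranomafana National Park,True,36,10.4,22.2,7(5–7)/3,,,100.0,AY848444,Boophis luciae,adult_reference,described_species,False,True,True,free,,2,adherent,,False
Boophis sambirano,,,FG/MV 2002.1902,ZSM 672/2004,EU717861,Manongarivo Special Reserve,Manongarivo Special Reserve,True,25,6.5,12.7,8(6–8)/3,248,,96.0,AY848544,Boophis sambirano,adult_reference,described_species,True,True,False,free,U,2,adherent,,False
Boophis mandraka,38,Vieites et al. 2009,ZCMV 4261,ZSM 456/2007,FJ559153,Ranomafana National Park,Manongarivo Special Reserve,False,26,7.6,15.8,8(6–8)/3,,,93.3,EU717863,Boophis sambirano,adult_reference,described_species,False,True,False,free,U,2,adherent,,False
Boophis mandraka,46,JQ518195,ZCMV 3479,ZSM 1784/2007,JQ518195,An'Ala,Ilampy,False,25,6.8,14.3,8(6–8)/3,,,90.4,AY848542,Boophis sp. aff. mandraka,adult_reference,described_species,False,True,False,free,U,2,adherent,,False
Boophis sambirano,47,JQ518203,ZCMV 13105,ZSM 482/2010,JQ518203,Anjingo river,Manongarivo Special Reserve,False,27,13.5,27.1,8(6–8)/3,377,,97.0,EU717861,Boophis sambirano,tadpole_reference,described_species,False,True,False,free,U,2,adherent,Boophis sambirano [Ca48],False
Boophis sambirano,48,JQ518205,ZCMV 13109,ZSM 485/2010,JQ518205,Anjingo river,Manongarivo Special Reserve,False,27,12.7,24.7,8(6–8)/3,336,,94.0,EU717861,Boophis sambirano,tadpole_reference,described_species,False,True,False,free,U,2,adherent,Boophis sambirano [Ca47],False
Boophis sambirano,49,JQ518208,ZCMV 13155,ZSM 528/2010,JQ518208,Ankijagna Lalagna,Manongarivo Special Reserve,False,27,11.7,26.7,8(6–8)/3,,,94.1,EU717861,Boophis sambirano,tadpole_reference,described_species,False,True,False,free,U,2,adherent,Boophis sambirano [Ca50],True
Boophis sambirano,50,JQ518211,ZCMV 13172,ZSM 545/2010,JQ518211,Ambinanitelo,Manongarivo Special Reserve,False,27,11.7,25.7,8(6–8)/3,,,94.9,EU717861,Boophis sambirano,tadpole_reference,described_species,False,True,False,free,U,2,adherent,Boophis sambirano [Ca49],False
Boophis marojezensis,,,FGZC 2277,ZSM 1528/2007,JQ518196,Marojejy National Park,Marojejy National Park,True,27,7.1,18.3,7(5–7)/3,290,606,99.8,FJ559127,Boophis marojezensis,adult_reference,described_species,False,False,True,free,U,3,suctorial,Boophis marojezensis [Ca25]; Boophis marojezensis [Ca26],False
Boophis marojezensis,25,Vieites et al. 2009,FGZC 2929,ZSM 1611/2007,FJ559146,Marojejy National Park,Vohidrazana,False,29,7.8,18.5,7(5–7)/3,222,315,97.0,AY848596,Boophis marojezensis,adult_reference,described_species,False,False,True,free,U,3,suctorial,Boophis marojezensis; Boophis marojezensis [Ca26],True
Boophis marojezensis,26,Vieites et al. 2009,FGZC 2930,ZSM 1612/2007,JQ518197,Marojejy National Park,Tsaratanana,False,29,8.8,20.6,7(5–7)/3,234,430,96.6,AY848595,Boophis marojezensis,adult_reference,described_species,False,False,True,free,U,3,suctorial,Boophis marojezensis; Boophis marojezensis [Ca25],False
Boophis marojezensis,51,JQ518198,ZCMV 3691,ZSM 267/2008,JQ518198,Ranomafana National Park,Vohiparara,True,25,6.0,20.0,7(5–7)/3,297,309,99.7,AY848594,Boophis marojezensis,adult_reference,unassigned_lineage,False,False,True,free,U,3,suctorial,,False
Boophis marojezensis,52,JQ518215,ZCMV 13168,ZSM 541/2010,JQ518215,Ambinanitelo,Tsaratanana Strict Nature Reserve,False,28,10.5,26.1,7(5–7)/3,258,522,100.0,AY848595,Boophis marojezensis,adult_reference,unassigned_lineage,False,False,True,free,U,3,suctorial,,False
Boophis marojezensis,53,JQ518216,ZCMV 13200,ZSM 573/2010,JQ518216,Tsaratanana Strict Nature Reserve,Marojejy National Park,False,27,9.6,23.0,7(5–7)/3,243,452,98.8,FJ559127,Boophis marojezensis,adult_reference,described_species,False,False,True,free,U,3,suctorial,,False
Boophis vittatus,,,FGZC 2238,ZSM 1906/2007,JQ518200,Marojejy National Park,Marojejy National Park,True,29,7.8,18.5,7(5–7)/3,289,326,100.0,FJ559158,Boophis vittatus,adult_reference,described_species,False,False,True,free,U,3,suctorial,,False
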