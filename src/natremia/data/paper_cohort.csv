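record_id,sex,age_y,weight_kg,tbw_l,infusate_volume_l,infusate_percent_nacl,na_initial_mmol_l,na_final_mmol_l,urine_osm_mosm_l,causative_condition
1,male,79,57,34,1.5,0.9,133,131,766,Citalopram use
2,male,78,62,37,1.0,0.9,132,131,702,Pain due to leg ischemia
3,male,74,60,30,1.0,0.9,130,129,614,Pneumonia
4,male,74,60,30,0.5,0.9,129,128,689,Pneumonia
5,male,59,77,40,1.0,0.9,129,128,890,Quetiapine use
6,female,66,66,33,1.0,0.9,131,130,569,Non-small cell lung carcinoma
7,female,78,50,25,1.0,0.9,128,127,660,Pain due to hip fracture
8,female,82,54,27,1.5,0.9,128,128,496,Unknown
9,female,78,50,25,0.10,2.5,127,128,677,Pain due to hip fracture
10,male,59,100,60,0.15,2.5,106,107,336,Pneumonia
11,female,87,86,43,1.5,0.9,131,132,386,Unknown
12,male,69,79,47,0.15,2.5,122,123,645,Psychosis
13,male,69,79,47,0.10,2.5,123,124,559,Psychosis
14,female,84,70,35,0.10,2.5,121,122,354,Pneumonia
15,female,85,58,29,0.15,2.5,122,124,345,Viral respiratory tract infection
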