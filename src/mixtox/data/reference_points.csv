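compound,group,rp_value_ug_per_kg_bw_d,rp_type,species,duration_class,extra_af,is_critical,hbgv_ug_per_kg_bw_d,effect
CIT,kidney,20,NOAEL,rat,subchronic,,True,,no nephrotoxicity at highest dose tested
FB1,kidney,200,NOAEL,rat,chronic,,False,2,kidney lesions (renal tubule epithelium)
NIV,kidney,660,NOAEL,mouse,chronic,,False,,decreased kidney weight
OTA,kidney,4.73,BMDL10,pig,subchronic,,True,,non-neoplastic kidney lesions
PAT,kidney,800,NOAEL,rat,subchronic,,False,,slight impairment in kidney function
FB1,liver,100,BMDL10,mouse,chronic,,True,1,megalocytic hepatocytes
ZEN,liver,1000,LOEL,rat,chronic,,False,,hepatocellular cytoplasmatic vacuolization
DAS,haematological,65,NOAEL,human,clinical_nonchronic,,True,0.65,leukopenia and agranulocytosis
NIV,haematological,350,BMDL05,rat,subchronic,,True,,reduced white blood cell count
MON,haematological,200,BMDL05,pig,subchronic,,True,1,decreased haematocrit and haemoglobin
T2HT2,haematological,3.33,BMDL10,rat,subchronic,,True,0.02,reduced leukocyte count
DAS,wbc,65,NOAEL,human,clinical_nonchronic,,True,0.65,leukopenia and agranulocytosis
NIV,wbc,350,BMDL05,rat,subchronic,,True,,reduced white blood cell count
T2HT2,wbc,3.33,BMDL10,rat,subchronic,,True,0.02,reduced leukocyte count
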