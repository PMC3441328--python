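drug,atc_main_group,first_month,max_monthly_per_100k,pq_ratio,r2,adoption_time_years,external_dominant
Esomeprazole,Alimentary tract and metabolism,Mar 2002,2755,5.87e-1,0.990,8.67,False
Clarithromycin,Alimentary tract and metabolism,Dec 1998,384,1.50e9,0.865,14.08,True
Granisetron,Alimentary tract and metabolism,Dec 2003,45,3.30e-2,0.986,5.58,False
Ursodeoxycholic acid,Alimentary tract and metabolism,Jun 2000,13,8.50e9,0.948,9.75,True
Balsalazide,Alimentary tract and metabolism,Mar 2005,9,1.08e-1,0.995,4.58,False
Insulin lispro,Alimentary tract and metabolism,Jun 1996,30,4.52e-1,0.973,6.75,False
Insulin glargine,Alimentary tract and metabolism,May 2006,113,5.57e-1,0.961,5.50,False
Glimepiride,Alimentary tract and metabolism,Jun 2000,263,3.40e-2,0.981,2.42,False
Rosiglitazone,Alimentary tract and metabolism,Jun 2003,228,3.40e-2,0.969,4.17,False
Pioglitazone,Alimentary tract and metabolism,Jun 2003,226,1.21e-1,0.912,8.83,False
Acarbose,Alimentary tract and metabolism,Jun 1997,38,6.20e-2,0.991,2.25,False
Enoxaparin,Blood and blood forming organs,Nov 1993,123,4.00e-3,0.990,14.42,False
Clopidogrel,Blood and blood forming organs,Apr 1999,1327,2.69e-1,0.994,11.33,False
Ticlopidine,Blood and blood forming organs,Nov 1992,15,1.90e-2,0.976,6.08,False
Dipyridamole,Blood and blood forming organs,Mar 1999,74,1.10e-2,0.962,1.17,False
Abciximab,Blood and blood forming organs,Dec 1995,2,5.00e-2,0.965,5.83,False
Tirofiban,Blood and blood forming organs,Jun 1999,1,3.37e-1,0.979,4.92,False
Nicorandil,Cardiovascular system,Sep 1997,110,6.97e-1,0.979,13.58,False
Eplerenone,Cardiovascular system,Sep 2005,5,1.19e-1,0.986,5.00,False
Bisoprolol,Cardiovascular system,Mar 2002,211,2.80e-2,0.983,9.08,False
Carvedilol,Cardiovascular system,Dec 1997,256,1.39e-1,0.991,9.50,False
Amlodipine,Cardiovascular system,Mar 1993,1378,1.86e9,0.863,12.92,True
Lisinopril,Cardiovascular system,Apr 1992,744,1.79e-1,0.992,4.92,False
Perindopril,Cardiovascular system,Mar 1992,3174,4.60e-2,0.991,18.08,False
Ramipril,Cardiovascular system,Apr 1992,1550,5.60e-2,0.976,14.83,False
Quinapril,Cardiovascular system,Sep 1992,453,8.00e-3,0.953,7.25,False
Fosinopril,Cardiovascular system,Apr 1992,491,2.45,0.933,8.75,True
Trandolapril,Cardiovascular system,Nov 1994,424,6.90e-2,0.980,4.58,False
Eprosartan,Cardiovascular system,Apr 1999,98,3.50e-2,0.983,6.25,False
Irbesartan,Cardiovascular system,Dec 1997,3333,6.51e-1,0.992,9.33,False
Candesartan,Cardiovascular system,Sep 1998,1640,1.02e-1,0.995,11.83,False
Telmisartan,Cardiovascular system,Jun 1999,1535,1.07e-1,0.969,12.25,False
Pravastatin,Cardiovascular system,Jan 1993,895,9.20e-2,0.991,10.58,False
Fluvastatin,Cardiovascular system,Sep 1995,223,2.80e-2,0.952,1.83,False
Atorvastatin,Cardiovascular system,Sep 1997,5096,8.67e-1,0.987,13.42,False
Rosuvastatin,Cardiovascular system,Jun 2006,1967,3.60e-2,0.990,3.83,False
Fenofibrate,Cardiovascular system,Mar 2004,250,3.00e-2,0.991,6.00,False
Ezetimibe,Cardiovascular system,Mar 2004,419,1.30,0.974,6.17,True
Fluconazole,Dermatologicals,May 1992,11,2.83e8,0.909,23.33,True
Imiquimod,Dermatologicals,Nov 2005,14,1.33e-1,0.952,1.42,False
Fluticasone,Dermatologicals,Mar 1995,552,1.20e-2,0.979,5.17,False
Tacrolimus,Dermatologicals,Mar 2003,6,2.46e-1,0.967,9.92,False
Finasteride,Dermatologicals,Jun 1995,25,1.71,0.838,18.50,True
Raloxifene,Genito urinary system and sex hormones,May 1999,153,4.80e-2,0.994,2.75,False
Alprostadil,Genito urinary system and sex hormones,Jun 1995,64,2.00e-3,0.989,2.42,False
Roxithromycin,Antiinfectives for systemic use,Jun 1992,1244,7.50e-1,0.972,5.33,False
Azithromycin,Antiinfectives for systemic use,Jan 1995,47,1.26e-1,0.916,17.17,False
Itraconazole,Antiinfectives for systemic use,Jun 1997,3,1.94e8,0.955,8.75,True
Famciclovir,Antiinfectives for systemic use,Jun 1995,64,4.79e11,0.902,17.08,True
Valaciclovir,Antiinfectives for systemic use,Mar 1996,160,1.54e-1,0.997,13.50,False
Temozolomide,Antineoplastic and immunomodulating agents,Sep 1999,5,5.98e-1,0.910,12.33,False
Gemcitabine,Antineoplastic and immunomodulating agents,Dec 1995,9,2.08e-1,0.974,8.50,False
Capecitabine,Antineoplastic and immunomodulating agents,Jun 1999,9,2.22,0.928,8.58,True
Vinorelbine,Antineoplastic and immunomodulating agents,Jun 1998,1,4.10e-2,0.980,2.00,False
Paclitaxel,Antineoplastic and immunomodulating agents,May 1994,9,2.96e-1,0.942,17.92,False
Docetaxel,Antineoplastic and immunomodulating agents,Mar 1996,9,5.39e-1,0.850,19.25,False
Oxaliplatin,Antineoplastic and immunomodulating agents,Jun 2001,8,4.46e-1,0.971,5.00,False
Rituximab,Antineoplastic and immunomodulating agents,Sep 1998,18,1.85e-1,0.983,10.50,False
Imatinib,Antineoplastic and immunomodulating agents,Jul 2001,9,1.70e-2,0.976,1.92,False
Irinotecan,Antineoplastic and immunomodulating agents,Dec 1999,5,8.00e-3,0.865,1.08,False
Nilutamide,Antineoplastic and immunomodulating agents,Dec 1996,2,3.10e-2,0.977,1.92,False
Anastrozole,Antineoplastic and immunomodulating agents,Mar 1997,89,2.00e-3,0.982,12.42,False
Letrozole,Antineoplastic and immunomodulating agents,Dec 1997,51,6.00e-2,0.928,15.42,False
Exemestane,Antineoplastic and immunomodulating agents,Aug 2000,9,2.03e-1,0.921,11.67,False
Interferon beta1a,Antineoplastic and immunomodulating agents,Sep 1998,16,2.87e7,0.977,9.75,True
Interferon alfa2a,Antineoplastic and immunomodulating agents,Jul 1992,1,1.20e-2,0.900,8.33,False
Leflunomide,Antineoplastic and immunomodulating agents,Sep 1999,78,2.87e9,0.948,12.58,True
Etanercept,Antineoplastic and immunomodulating agents,Mar 2003,27,8.60e-2,0.989,7.58,False
Adalimumab,Antineoplastic and immunomodulating agents,Dec 2003,36,1.90e-2,0.980,6.92,False
Rofecoxib,Musculo-skeletal system,Jun 2000,1281,1.40e-2,0.963,1.75,False
Celecoxib,Musculo-skeletal system,Jun 1999,1806,2.00e-3,0.981,1.58,False
Alendronic acid,Musculo-skeletal system,Jun 1996,955,9.00e-3,0.991,8.25,False
Risedronic acid,Musculo-skeletal system,Sep 2000,583,6.20e-2,0.993,8.42,False
Fentanyl,Nervous system,Mar 1999,203,6.00e-3,0.910,12.25,False
Tramadol,Nervous system,Apr 1999,954,1.10e-2,0.962,4.33,False
Oxcarbazepine,Nervous system,May 1999,6,3.84,0.955,8.42,True
Lamotrigine,Nervous system,Jul 1994,146,7.11e-1,0.984,17.17,False
Topiramate,Nervous system,Mar 1997,87,1.80e-1,0.921,18.25,False
Gabapentin,Nervous system,Jul 1994,75,8.10e-2,0.974,14.67,False
Flupentixol,Nervous system,Mar 1994,8,4.99e-1,0.988,5.08,False
Zuclopenthixol,Nervous system,Jun 1996,10,1.21e-1,0.956,6.83,False
Olanzapine,Nervous system,Mar 1997,391,1.87,0.961,11.08,True
Quetiapine,Nervous system,Jun 2000,262,5.90e-2,0.950,11.75,False
Amisulpride,Nervous system,Mar 2002,36,8.60e-2,0.952,2.42,False
Risperidone,Nervous system,Sep 1994,268,9.10e-2,0.927,17.67,False
Aripiprazole,Nervous system,Dec 2003,47,5.50,0.975,5.50,True
Citalopram,Nervous system,Sep 1997,757,6.30e-2,0.994,5.50,False
Paroxetine,Nervous system,Mar 1994,581,1.33e-1,0.996,5.92,False
Sertraline,Nervous system,Mar 1994,1181,3.55e-1,0.985,9.67,False
Fluvoxamine,Nervous system,Mar 1997,183,2.21e-1,0.997,8.00,False
Venlafaxine,Nervous system,Mar 1996,1167,1.15e-1,0.990,12.83,False
Methylphenidate,Nervous system,Feb 2005,156,6.50e-2,0.992,3.92,False
Donepezil,Nervous system,Apr 1999,102,3.83e-1,0.955,6.75,False
Rivastigmine,Nervous system,Mar 2000,13,1.00e-3,0.946,1.42,False
Galantamine,Nervous system,Jun 2001,47,1.10e-1,0.996,4.92,False
Acamprosate,Nervous system,Jun 1999,12,2.40e-2,0.944,0.92,False
Riluzole,Nervous system,Feb 2003,3,3.49e5,0.975,6.08,True
Nedocromil,Respiratory system,Nov 1994,115,5.00e-2,0.986,2.08,False
Salmeterol,Respiratory system,Sep 1994,1362,1.10e-2,0.944,10.00,False
Formoterol,Respiratory system,Dec 1996,644,8.90e-2,0.948,16.75,False
Tiotropium,Respiratory system,Sep 2002,748,3.537,0.969,8.50,True
Montelukast,Respiratory system,Sep 2002,78,4.82,0.969,7.08,True
Latanoprost,Sensory organs,Dec 1997,689,2.99e9,0.923,7.92,True
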