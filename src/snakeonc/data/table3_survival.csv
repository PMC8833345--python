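row,species,survival_months,treatment,radiation,nsaid_short,table1_diagnoses,printed_tumors
1,Boa constrictor,0.25,none,0,0,Neuroendocrine Tumor,Benign carcinoid tumor
2,Boa constrictor,1,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
3,Lichanura trivirgata,7,surgery_only,0,0,Histiocytic Sarcoma,Histiocytic sarcoma
4,Sanzinia madagascariensis,22,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
5,Heterodon nasicus,10,none,0,0,Hepatocellular Carcinoma,Hepatocellular carcinoma
6,Heterodon nasicus,6,surgery_only,0,1,Soft Tissue Sarcoma,Soft tissue sarcoma
7,Heterodon platirhinos,15.5,none,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
8,Lampropeltis getula,10.5,none,0,0,Soft Tissue Sarcoma|Hepatic Adenocarcinoma,"Soft tissue sarcoma, Hepatocellular adenocarcinoma"
9,Lampropeltis getula,8,surgery_only,0,0,Soft Tissue Sarcoma|Chromatophoroma (iridophoroma),"Soft tissue sarcoma, Chromatophoroma (uncharacterized)"
10,Nerodia sipedon,5,surgery_only,0,1,Soft Tissue Sarcoma|Malignant Chromatophoroma (iridophoroma),"Soft tissue sarcoma, Malignant chromatophoroma"
11,Nerodia sipedon,1,surgery_only,0,0,Malignant Chromatophoroma (uncharacterized),Malignant chromatophoroma
12,Nerodia sipedon,0.5,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
13,Pantherophis guttatus,2,none,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
14,Pantherophis guttatus,12,surgery_and_chemotherapy,1,1,Soft Tissue Sarcoma,Soft tissue sarcoma
15,Pantherophis guttatus,2,surgery_only,0,0,Hemangiosarcoma,Hemangiosarcoma
16,Pantherophis guttatus,108,surgery_only,0,1,Soft Tissue Sarcoma,Soft tissue sarcoma
17,Pantherophis guttatus,18,surgery_only,1,0,Soft Tissue Sarcoma,Soft tissue sarcoma
18,Pantherophis guttatus,5.5,surgery_and_chemotherapy,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
19,Pantherophis obsoletus or alleghaniensis,7,surgery_only,0,1,Gastrointestinal Adenocarcinoma,Colonic adenocarcinoma
20,Pantherophis obsoletus or alleghaniensis,15,none,0,0,Chondrosarcoma,Chondrosarcoma
21,Pantherophis obsoletus or alleghaniensis,1,none,0,0,Lymphoma/Leukemia,Leukemia
22,Pantherophis obsoletus or alleghaniensis,6,supportive_care,0,1,Osteosarcoma,Osteosarcoma
23,Pantherophis obsoletus or alleghaniensis,4,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
24,Pituophis catenifer,1,none,0,0,Hepatobiliary Carcinoma,Hepatocellular carcinoma
25,Thamnophis cyrtopsis,5.5,surgery_only,0,0,Malignant Chromatophoroma (Melanoma),Malignant chromatophoroma
26,Thamnophis radix,13,surgery_only,1,0,Malignant Chromatophoroma (Melanoma),Malignant chromatophoroma
27,Thamnophis radix,1,surgery_only,0,0,Granulosa Cell Tumor,Malignant granulosa cell tumor
28,Thamnophis sirtalis,9,unknown,0,0,Biliary Cystadenoma|Squamous Cell Carcinoma,Squamous cell carcinoma
29,Hemachatus haemachatus,0.75,none,0,0,Lymphoma/Leukemia,Lymphoma
30,Hydrodynastes gigas,71,surgery_only,0,0,Renal Adenocarcinoma|Pancreatic Adenocarcinoma,Renal and Pancreatic adenocarcinoma
31,Naja pallida,35,surgery_only,0,0,Renal Adenocarcinoma,Renal carcinoma/adenocarcinoma
32,Ophiophagus hannah,11,chemotherapy,0,0,Lymphoma/Leukemia,Lymphoma
33,Antaresia childreni,3,surgery_only,0,0,Lymphoma/Leukemia|Soft Tissue Sarcoma,"Lymphoma, Soft tissue sarcoma"
34,Morelia spilota,2.5,surgery_only,0,0,Esophageal Carcinoma,Esophageal carcinoma
35,Morelia viridis,7,unknown,0,0,Squamous Cell Carcinoma,Squamous cell carcinoma
36,Python bivittatus,1,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
37,Python regius,84,surgery_and_chemotherapy,0,1,Squamous Cell Carcinoma,Squamous cell carcinoma
38,Agkistrodon piscivorus,0.25,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
39,Bothriechis schlegelii,16,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
40,Bothriechis schlegelii,5,none,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
41,Crotalus adamanteus,20,surgery_and_chemotherapy,0,0,Lymphoma/Leukemia,Lymphoma
42,Crotalus adamanteus,18.5,surgery_only,0,0,Squamous Cell Carcinoma,Squamous cell carcinoma
43,Crotalus adamanteus,7,surgery_only,0,0,Hemangiosarcoma|Sertoli Cell Tumor,"Hemangiosarcoma, Sertoli cell tumor (uncharacterized)"
44,Crotalus cerastes,1,none,0,0,Chromatophoroma (Melanophoroma)|Hepatic Adenoma,"Chromatophoroma (uncharacterized), Hepatobiliary adenoma"
45,Crotalus horridus,0.25,none,0,0,Ovarian Carcinoma,Ovarian carcinoma
46,Crotalus horridus,0.25,none,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
47,Crotalus horridus,1,surgery_only,0,0,Soft Tissue Sarcoma,Soft tissue sarcoma
48,Crotalus horridus,24,surgery_only,0,0,Lipoma,Lipoma
49,Crotalus lepidus,1,none,0,0,Malignant Chromatophoroma (Melanophoroma)|Hepatic Adenoma,"Malignant chromatophoroma, Hepatobiliary adenoma"
50,Crotalus viridis,1,none,0,0,Hepatocellular Carcinoma|Soft Tissue Sarcoma,"Hepatocellular carcinoma, Soft tissue sarcoma"
51,Lachesis muta,3,none,0,0,Hepatocellular Carcinoma,Hepatocellular carcinoma/adenocarcinoma
52,Sistrurus catenatus,3.5,surgery_only,0,1,Osteosarcoma,Osteosarcoma
53,Trimeresurus sumatranus,0.36,none,0,0,Lymphoma/Leukemia,Lymphoma
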