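species,count,diagnosis,behavior
Acrantophis dumerili,1,Soft Tissue Sarcoma,malignant
Boa constrictor,1,Neuroendocrine Tumor,malignant
Boa constrictor,1,Soft Tissue Sarcoma,malignant
Chilabothrus granti,1,Thyroid Carcinoma,malignant
Chilabothrus granti,1,Hepatocellular Carcinoma,malignant
Eunectes murinus,1,Sertoli Cell Tumor,unspecified
Lichanura trivirgata,1,Pancreatic Adenoma,benign
Lichanura trivirgata,1,Undifferentiated Carcinoma,malignant
Lichanura trivirgata,1,Histiocytic Sarcoma,malignant
Sanzinia madagascariensis,1,Soft Tissue Sarcoma,malignant
Coelognathus radiatus,2,Hepatocellular Carcinoma,malignant
Coelognathus radiatus,1,Lymphoma/Leukemia,malignant
Coelognathus radiatus,1,Renal Adenocarcinoma,malignant
Elaphe taeniura,1,Soft Tissue Sarcoma,malignant
Heterodon nasicus,2,Hepatocellular Carcinoma,malignant
Heterodon nasicus,1,Soft Tissue Sarcoma,malignant
Heterodon platirhinos,1,Soft Tissue Sarcoma,malignant
Heterodon platirhinos,1,Malignant Chromatophoroma (unspecified),malignant
Lampropeltis getula,1,Renal Adenoma,benign
Lampropeltis getula,3,Soft Tissue Sarcoma,malignant
Lampropeltis getula,1,Renal Carcinoma,malignant
Lampropeltis getula,1,Hepatic Adenocarcinoma,malignant
Lampropeltis getula,1,Chromatophoroma (iridophoroma),unspecified
Lampropeltis triangulum,1,Gastrointestinal Adenocarcinoma,malignant
Leioheterodon madagascariensis,1,Osteosarcoma,malignant
Nerodia sipedon,3,Soft Tissue Sarcoma,malignant
Nerodia sipedon,1,Malignant Chromatophoroma (iridophoroma),malignant
Nerodia sipedon,1,Malignant Chromatophoroma (uncharacterized),malignant
Oreocryptophis porphyraceus,1,Hepatocellular Carcinoma,malignant
Pantherophis guttatus,1,Granulosa Cell Tumor,malignant
Pantherophis guttatus,1,Lymphoma/Leukemia,malignant
Pantherophis guttatus,7,Soft Tissue Sarcoma,malignant
Pantherophis guttatus,1,Osteosarcoma,malignant
Pantherophis guttatus,2,Hemangiosarcoma,malignant
Pantherophis obsoletus or alleghaniensis,5,Soft Tissue Sarcoma,malignant
Pantherophis obsoletus or alleghaniensis,1,Gastrointestinal Adenocarcinoma,malignant
Pantherophis obsoletus or alleghaniensis,1,Renal Carcinoma,malignant
Pantherophis obsoletus or alleghaniensis,1,Chondrosarcoma,malignant
Pantherophis obsoletus or alleghaniensis,4,Lymphoma/Leukemia,malignant
Pantherophis obsoletus or alleghaniensis,1,Osteosarcoma,malignant
Pantherophis obsoletus or alleghaniensis,1,Granulosa Cell Tumor,unspecified
Pituophis catenifer,2,Hepatobiliary Carcinoma,malignant
Pituophis lineaticollis,1,Undifferentiated Carcinoma,malignant
Pituophis ruthveni,1,Soft Tissue Sarcoma,malignant
Rhamphiophis oxyrhynchus,1,Neuroendocrine Tumor,malignant
Rhinocheilus lecontei,1,Gastrointestinal Adenocarcinoma,malignant
Rhynchophis boulengeri,1,Lymphoma/Leukemia,malignant
Salvadora bairdi,1,Renal Adenocarcinoma,malignant
Thamnophis cyrtopsis,1,Malignant Chromatophoroma (Melanoma),malignant
Thamnophis exsul,2,Biliary Cystadenoma,benign
Thamnophis radix,1,Malignant Chromatophoroma (Melanoma),malignant
Thamnophis radix,1,Granulosa Cell Tumor,malignant
Thamnophis radix,1,Undifferentiated Carcinoma,malignant
Thamnophis radix,1,Hepatocellular Carcinoma,malignant
Thamnophis sirtalis,1,Biliary Cystadenoma,benign
Thamnophis sirtalis,1,Squamous Cell Carcinoma,malignant
Trimorphodon lambda,1,Renal Carcinoma,malignant
Hemachatus haemachatus,1,Lymphoma/Leukemia,malignant
Hemachatus haemachatus,1,Gastrointestinal Adenocarcinoma,malignant
Hydrodynastes gigas,1,Renal Adenocarcinoma,malignant
Hydrodynastes gigas,1,Pancreatic Adenocarcinoma,malignant
Naja pallida,1,Renal Adenocarcinoma,malignant
Ophiophagus hannah,1,Granulosa Cell Tumor,benign
Ophiophagus hannah,1,Lymphoma/Leukemia,malignant
Ophiophagus hannah,1,Undifferentiated Adenocarcinoma,malignant
Antaresia childreni,1,Lymphoma/Leukemia,malignant
Antaresia childreni,1,Soft Tissue Sarcoma,malignant
Liasis mackloti,1,Lymphoma/Leukemia,malignant
Malayopython reticulatus,1,Hepatocellular Carcinoma,malignant
Morelia spilota,1,Esophageal Carcinoma,malignant
Morelia viridis,1,Squamous Cell Carcinoma,malignant
Python bivittatus,1,Soft Tissue Sarcoma,malignant
Python regius,1,Squamous Cell Carcinoma,malignant
Python regius,1,Gastrointestinal Adenocarcinoma,malignant
Python regius,1,Chromatophoroma (melanophoroma),unspecified
Agkistrodon contortrix,2,Hepatocellular Adenoma,benign
Agkistrodon contortrix,1,Lymphoma/Leukemia,malignant
Agkistrodon piscivorus,1,Soft Tissue Sarcoma,malignant
Agkistrodon piscivorus,1,Lymphoma/Leukemia,malignant
Atheris squamigera,1,Hepatic Cystadenocarcinoma,malignant
Atheris squamigera,1,Oviduct Adenocarcinoma,malignant
Bitis arietans,1,Renal Carcinoma,malignant
Bitis arietans,1,Soft Tissue Sarcoma,malignant
Bitis nasicornis,1,Renal Adenocarcinoma,malignant
Bitis nasicornis,1,Cholangiocellular Carcinoma,malignant
Bitis nasicornis,1,Renal Carcinoma,malignant
Bitis nasicornis,1,Lymphoma/Leukemia,malignant
Bothriechis rowleyi,1,Soft Tissue Sarcoma,malignant
Bothriechis rowleyi,1,Squamous Cell Carcinoma,malignant
Bothriechis schlegelii,2,Soft Tissue Sarcoma,malignant
Bothrops asper,1,Renal Cystadenoma,benign
Bothrops asper,1,Soft Tissue Sarcoma,malignant
Crotalus adamanteus,2,Soft Tissue Sarcoma,malignant
Crotalus adamanteus,1,Lymphoma/Leukemia,malignant
Crotalus adamanteus,1,Squamous Cell Carcinoma,malignant
Crotalus adamanteus,1,Hemangiosarcoma,malignant
Crotalus adamanteus,1,Sertoli Cell Tumor,unspecified
Crotalus atrox,1,Renal Adenocarcinoma,malignant
Crotalus atrox,1,Cholangiocellular Carcinoma,malignant
Crotalus atrox,1,Sertoli Cell Tumor,unspecified
Crotalus cerastes,1,Hepatic Adenoma,benign
Crotalus cerastes,1,Chromatophoroma (Melanophoroma),unspecified
Crotalus culminatus,1,Soft Tissue Sarcoma,malignant
Crotalus culminatus,1,Biliary Adenocarcinoma,malignant
Crotalus horridus,1,Lipoma,benign
Crotalus horridus,3,Soft Tissue Sarcoma,malignant
Crotalus horridus,1,Ovarian Carcinoma,malignant
Crotalus lepidus,1,Hepatic Adenoma,benign
Crotalus lepidus,1,Malignant Chromatophoroma (Melanophoroma),malignant
Crotalus molossus,1,Soft Tissue Sarcoma,malignant
Crotalus molossus,1,Hepatocellular Carcinoma,malignant
Crotalus viridis,1,Hepatocellular Carcinoma,malignant
Crotalus viridis,1,Soft Tissue Sarcoma,malignant
Lachesis muta,2,Hepatocellular Carcinoma,malignant
Montivipera raddei,1,Pancreatic Carcinoma,malignant
Protobothrops flavoviridis,1,Soft Tissue Sarcoma,malignant
Sistrurus catenatus,1,Osteosarcoma,malignant
Sistrurus miliarius,1,Pancreatic Adenoma,benign
Sistrurus miliarius,1,Biliary Adenocarcinoma,malignant
Trimeresurus flavomaculatus,1,Lymphoma/Leukemia,malignant
Trimeresurus mcgregori,1,Soft Tissue Sarcoma,malignant
Trimeresurus sumatranus,1,Lymphoma/Leukemia,malignant
Vipera transcaucasiana,1,Soft Tissue Sarcoma,malignant
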