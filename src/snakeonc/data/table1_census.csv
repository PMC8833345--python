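species,common_name,family,total_individuals,cases
Acrantophis dumerili,Dumeril's Ground Boa,Boidae,41,1
Boa constrictor,Boa Constrictor,Boidae,14,2
Chilabothrus granti,Virgin Islands Boa,Boidae,13,1
Eunectes murinus,Green Anaconda,Boidae,23,1
Lichanura trivirgata,Rosy Boa,Boidae,19,3
Sanzinia madagascariensis,Madagascar Tree Boa,Boidae,5,1
Coelognathus radiatus,Radiated Ratsnake,Colubridae,101,4
Elaphe taeniura,Taiwan Beauty Snake,Colubridae,9,1
Heterodon nasicus,Western Hog-Nosed Snake,Colubridae,29,3
Heterodon platirhinos,Eastern Hog-Nosed Snake,Colubridae,8,2
Lampropeltis getula,Kingsnake,Colubridae,28,5
Lampropeltis triangulum,Eastern Milksnake,Colubridae,56,1
Leioheterodon madagascariensis,Madagascar Giant Hognose Snake,Colubridae,78,1
Nerodia sipedon,Common Or Northern Watersnake,Colubridae,13,4
Oreocryptophis porphyraceus,Black-Banded Trinket Snake,Colubridae,19,1
Pantherophis guttatus,Corn Snake,Colubridae,115,11
Pantherophis obsoletus or alleghaniensis,Ratsnake,Colubridae,189,14
Pituophis catenifer,Gophersnake or Bullsnake,Colubridae,37,2
Pituophis lineaticollis,Middle American Gophersnake,Colubridae,4,1
Pituophis ruthveni,Louisiana Pinesnake,Colubridae,42,1
Rhamphiophis oxyrhynchus,Rufous-Beaked Snake,Colubridae,7,1
Rhinocheilus lecontei,Long-Nosed Snake,Colubridae,6,1
Rhynchophis boulengeri,Rhinoceros Snake,Colubridae,19,1
Salvadora bairdi,Baird's Patchnose Snake,Colubridae,21,1
Thamnophis cyrtopsis,Black-Necked Gartersnake,Colubridae,1,1
Thamnophis exsul,Exiled Gartersnake,Colubridae,19,2
Thamnophis radix,Plains Gartersnake,Colubridae,500,4
Thamnophis sirtalis,Common Gartersnake,Colubridae,1,1
Trimorphodon lambda,Sonoran Lyresnake,Colubridae,4,1
Hemachatus haemachatus,Ringhals Cobra,Elapidae,14,2
Hydrodynastes gigas,False Water Cobra,Elapidae,72,1
Naja pallida,Red Spitting Cobra,Elapidae,26,1
Ophiophagus hannah,King Cobra,Elapidae,13,2
Antaresia childreni,Children's Python,Pythonidae,44,1
Liasis mackloti,Macklot's Python,Pythonidae,2,1
Malayopython reticulatus,Reticulated Python,Pythonidae,4,1
Morelia spilota,Carpet Python,Pythonidae,8,1
Morelia viridis,Green Tree Python,Pythonidae,59,1
Python bivittatus,Burmese Python,Pythonidae,8,1
Python regius,Ball Python,Pythonidae,19,2
Agkistrodon contortrix,Copperhead,Viperidae,8,3
Agkistrodon piscivorus,Cottonmouth,Viperidae,11,2
Atheris squamigera,African Bush Viper,Viperidae,27,2
Bitis arietans,Puff Adder,Viperidae,4,2
Bitis nasicornis,Rhinoceros Viper,Viperidae,51,3
Bothriechis rowleyi,Rowley's Palm Pit Viper,Viperidae,48,2
Bothriechis schlegelii,Eyelash Viper,Viperidae,45,2
Bothrops asper,Terciopelo,Viperidae,41,1
Crotalus adamanteus,Eastern Diamond-Backed Rattlesnake,Viperidae,19,5
Crotalus atrox,Western Diamond-Backed Rattlesnake,Viperidae,21,2
Crotalus cerastes,Sidewinder,Viperidae,5,1
Crotalus culminatus,Northwestern Neotropical Rattlesnake,Viperidae,55,2
Crotalus horridus,Timber Rattlesnake,Viperidae,22,5
Crotalus lepidus,Rock Rattlesnake,Viperidae,7,1
Crotalus molossus,Black-Tailed Rattlesnake,Viperidae,5,1
Crotalus viridis,Prairie Rattlesnake,Viperidae,5,1
Lachesis muta,South American Bushmaster,Viperidae,13,2
Montivipera raddei,Armenian Viper,Viperidae,13,1
Protobothrops flavoviridis,Habu,Viperidae,6,1
Sistrurus catenatus,Eastern Massasauga,Viperidae,4,1
Sistrurus miliarius,Pygmy Rattlesnake,Viperidae,14,2
Trimeresurus flavomaculatus,Philippine Pit Viper,Viperidae,10,1
Trimeresurus mcgregori,McGregor's Tree Viper,Viperidae,44,1
Trimeresurus sumatranus,Sumatran Pit Viper,Viperidae,74,1
Vipera transcaucasiana,Transcaucasian Long-Nosed Viper,Viperidae,19,1
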