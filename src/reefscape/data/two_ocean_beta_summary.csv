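family,ocean,n_species,beta_jac_sd,beta_jtu_sd,beta_jne_sd,species,n_individuals,beta_gd
Acanthuridae,Caribbean,5,0.400,0.000,0.400,Acanthurus tractus,42,0.0350
Acanthuridae,WIO,42,0.410,0.207,0.203,Ctenochaetus striatus,69,0.0106
Labridae,Caribbean,32,0.406,0.000,0.406,Halichoeres garnoti,28,0.0149
Labridae,WIO,93,0.437,0.270,0.167,Gomphosus caeruleus,44,0.0172
Labridae,WIO,93,0.437,0.270,0.167,Halichoeres hortulanus,46,0.0202
Labridae,WIO,93,0.437,0.270,0.167,Hemigymnus fasciatus,44,0.0727
Mullidae,Caribbean,5,0.200,0.000,0.200,Mulloidichthys martinicus,53,-0.0100
Mullidae,WIO,17,0.286,0.118,0.168,Parupeneus macronemus,56,0.0354
Pomacentridae,Caribbean,21,0.284,0.111,0.172,Azurina cyanea,54,0.0147
Pomacentridae,Caribbean,21,0.284,0.111,0.172,Azurina multilineata,51,0.0370
Pomacentridae,Caribbean,21,0.284,0.111,0.172,Stegastes partitus,46,0.0216
Pomacentridae,WIO,71,0.487,0.185,0.302,Chromis atripectoralis,35,0.0654
Pomacentridae,WIO,71,0.487,0.185,0.302,Chromis ternatensis,49,0.0435
Pomacentridae,WIO,71,0.487,0.185,0.302,Chromis weberi,45,0.0631
Pomacentridae,WIO,71,0.487,0.185,0.302,Dascyllus aruanus,39,0.0522
Pomacentridae,WIO,71,0.487,0.185,0.302,Dascyllus carneus,55,0.0232
Pomacentridae,WIO,71,0.487,0.185,0.302,Dascyllus trimaculatus,40,0.0231
Tetraodontidae,Caribbean,12,0.429,0.333,0.095,Canthigaster rostrata,57,0.0116
Tetraodontidae,WIO,22,0.363,0.038,0.325,Canthigaster valentini,44,0.0284
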