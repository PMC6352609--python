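{
 "FC5": 0.56584,
 "FC3": 0.706648,
 "FC1": 0.56584,
 "FCz": 0.290512,
 "FC2": 0.095634,
 "FC4": 0.020186,
 "FC6": 0.002732,
 "C5": 0.800737,
 "C3": 1.0,
 "C1": 0.800737,
 "Cz": 0.411112,
 "C2": 0.135335,
 "C4": 0.028566,
 "C6": 0.003866,
 "CP5": 0.56584,
 "CP3": 0.706648,
 "CP1": 0.56584,
 "CPz": 0.290512,
 "CP2": 0.095634,
 "CP4": 0.020186,
 "CP6": 0.002732,
 "P3": 0.249352,
 "P1": 0.199666,
 "Pz": 0.102512,
 "P2": 0.033746,
 "P4": 0.007123,
 "PO3": 0.065729,
 "POz": 0.027022,
 "PO4": 0.001878,
 "O1": 0.014464,
 "Oz": 0.007426,
 "O2": 0.002445
}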