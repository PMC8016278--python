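{
 "m_beta": 0.29761727023783446,
 "c_beta": 6.716878734025004,
 "m_lambda": 0.30328588232815773,
 "c_lambda": 7.183180691168749,
 "a_m": 25.934554672488748,
 "b_m": 16.660554265302494,
 "per_P": {
  "36": [
   17.363651468448534,
   16.70979790953906,
   0.49429725789755546
  ],
  "64": [
   26.477868521715763,
   25.584646589126045,
   0.31634387926942514
  ],
  "100": [
   38.526962523864135,
   37.47042658396251,
   0.22169115227564146
  ],
  "144": [
   51.54583067975136,
   50.41836086505732,
   0.16389304853782585
  ],
  "196": [
   65.77596671926912,
   64.11448765087069,
   0.12615815943105638
  ]
 },
 "meta": {
  "resid_lambda": 0.042492271160509486,
  "resid_beta": 0.043166443840485964,
  "resid_m": 0.03333385392513881,
  "P_grid": [
   36,
   64,
   100,
   144,
   196
  ],
  "T": 1500.0,
  "dt": 0.2,
  "seed": 0,
  "conc_grid": [
   2.0,
   4.0,
   6.0,
   7.0,
   8.0,
   9.0,
   10.0,
   11.0,
   12.0,
   14.0,
   18.0,
   30.0
  ],
  "alpha": 16.0,
  "k_UB": 0.0005,
  "k_BU": 0.1
 }
}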