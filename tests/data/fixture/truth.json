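{
 "zones": {
  "P001": "A",
  "P002": "A",
  "P003": "A",
  "P004": "B",
  "P005": "A",
  "P006": "C",
  "P007": "B",
  "P008": "B",
  "P009": "C",
  "P010": "B",
  "P011": "C",
  "P012": "C"
 },
 "thresholds": [
  [
   "TD",
   24.070835181851674
  ],
  [
   "MWMT",
   24.262325771711826
  ]
 ],
 "proportions": {
  "biomass": [
   0.49,
   0.01,
   0.164,
   0.019,
   0.317
  ],
  "plant_height": [
   0.723,
   0.02,
   0.062,
   0.022,
   0.173
  ],
  "inflorescence_number": [
   0.548,
   0.01,
   0.03,
   0.024,
   0.388
  ],
  "leaf_length": [
   0.682,
   0.003,
   0.028,
   0.019,
   0.268
  ],
  "leaf_width": [
   0.375,
   0.016,
   0.109,
   0.03,
   0.47
  ],
  "leaf_ratio": [
   0.231,
   0.01,
   0.07,
   0.048,
   0.641
  ],
  "heading_date": [
   0.394,
   0.011,
   0.245,
   0.048,
   0.302
  ],
  "maturation_date": [
   0.696,
   0.013,
   0.073,
   0.014,
   0.204
  ],
  "survival": [
   0.37,
   0.057,
   0.132,
   0.066,
   0.375
  ]
 },
 "informative_variables": [
  "TD",
  "MWMT"
 ],
 "mildness": {
  "P001": 0.9583333333333334,
  "P002": 0.7083333333333334,
  "P003": 0.7916666666666666,
  "P004": 0.375,
  "P005": 0.875,
  "P006": 0.20833333333333334,
  "P007": 0.2916666666666667,
  "P008": 0.625,
  "P009": 0.125,
  "P010": 0.5416666666666666,
  "P011": 0.4583333333333333,
  "P012": 0.041666666666666664
 },
 "interaction_sd": {
  "biomass": {
   "P001": 26.978402498830224,
   "P002": 19.9405583687006,
   "P003": 22.286506412077138,
   "P004": 10.556766195194434,
   "P005": 24.632454455453683,
   "P006": 5.864870108441353,
   "P007": 8.210818151817895,
   "P008": 17.59461032532406,
   "P009": 3.5189220650648116,
   "P010": 15.248662281947515,
   "P011": 12.902714238570976,
   "P012": 1.1729740216882705
  },
  "plant_height": {
   "P001": 7.972043164849412,
   "P002": 5.89237973054087,
   "P003": 6.585600875310383,
   "P004": 3.119495151462813,
   "P005": 7.278822020079897,
   "P006": 1.733052861923785,
   "P007": 2.426274006693299,
   "P008": 5.199158585771356,
   "P009": 1.039831717154271,
   "P010": 4.505937441001841,
   "P011": 3.812716296232327,
   "P012": 0.346610572384757
  },
  "inflorescence_number": {
   "P001": 0.34727371584035527,
   "P002": 0.2566805725776539,
   "P003": 0.28687828699855433,
   "P004": 0.13588971489405205,
   "P005": 0.3170760014194548,
   "P006": 0.07549428605225116,
   "P007": 0.10569200047315161,
   "P008": 0.22648285815675345,
   "P009": 0.04529657163135069,
   "P010": 0.19628514373585296,
   "P011": 0.16608742931495252,
   "P012": 0.015098857210450229
  },
  "leaf_length": {
   "P001": 2.9767011942753006,
   "P002": 2.200170447942613,
   "P003": 2.459014030053509,
   "P004": 1.1647961194990306,
   "P005": 2.7178576121644045,
   "P006": 0.6471089552772392,
   "P007": 0.905952537388135,
   "P008": 1.9413268658317175,
   "P009": 0.3882653731663435,
   "P010": 1.682483283720822,
   "P011": 1.4236397016099263,
   "P012": 0.12942179105544782
  },
  "leaf_width": {
   "P001": 0.11826004185691802,
   "P002": 0.08740959615511332,
   "P003": 0.09769307805571488,
   "P004": 0.046275668552707046,
   "P005": 0.10797655995631644,
   "P006": 0.025708704751503917,
   "P007": 0.03599218665210548,
   "P008": 0.07712611425451174,
   "P009": 0.01542522285090235,
   "P010": 0.06684263235391018,
   "P011": 0.05655915045330861,
   "P012": 0.005141740950300783
  },
  "leaf_ratio": {
   "P001": 12.276246259432165,
   "P002": 9.07374723523247,
   "P003": 10.1412469099657,
   "P004": 4.803748536299542,
   "P005": 11.208746584698932,
   "P006": 2.6687491868330793,
   "P007": 3.7362488615663114,
   "P008": 8.006247560499238,
   "P009": 1.6012495120998476,
   "P010": 6.938747885766006,
   "P011": 5.871248211032774,
   "P012": 0.5337498373666159
  },
  "heading_date": {
   "P001": 8.426360753940907,
   "P002": 6.228179687695453,
   "P003": 6.96090670977727,
   "P004": 3.297271599368181,
   "P005": 7.693633731859089,
   "P006": 1.831817555204545,
   "P007": 2.5645445772863633,
   "P008": 5.495452665613635,
   "P009": 1.099090533122727,
   "P010": 4.762725643531817,
   "P011": 4.029998621449999,
   "P012": 0.366363511040909
  },
  "maturation_date": {
   "P001": 8.656885506154431,
   "P002": 6.398567548027188,
   "P003": 7.151340200736269,
   "P004": 3.387476937190864,
   "P005": 7.9041128534453495,
   "P006": 1.8819316317727024,
   "P007": 2.6347042844817836,
   "P008": 5.645794895318107,
   "P009": 1.1291589790636214,
   "P010": 4.8930222426090255,
   "P011": 4.140249589899945,
   "P012": 0.37638632635454045
  },
  "survival": {
   "P001": 3.4764487814489176,
   "P002": 2.569549099331809,
   "P003": 2.8718489933708446,
   "P004": 1.3603495231756635,
   "P005": 3.1741488874098813,
   "P006": 0.7557497350975908,
   "P007": 1.058049629136627,
   "P008": 2.267249205292772,
   "P009": 0.45344984105855446,
   "P010": 1.964949311253736,
   "P011": 1.6626494172146997,
   "P012": 0.15114994701951814
  }
 }
}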