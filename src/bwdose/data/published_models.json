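{
 "version": 1,
 "models": [
  {
   "cohort": "combined",
   "endpoint": "V10Gy",
   "terms": {
    "Vbw_cc": 0.969,
    "Pbw_3": 0.255
   },
   "intercept": -22.688,
   "r2": 0.94,
   "adjusted_r2": 0.938
  },
  {
   "cohort": "combined",
   "endpoint": "V15Gy",
   "terms": {
    "Vbw_cc": 0.938,
    "Pbw_3": 0.454
   },
   "intercept": -41.584,
   "r2": 0.901,
   "adjusted_r2": 0.899
  },
  {
   "cohort": "combined",
   "endpoint": "V20Gy",
   "terms": {
    "Vbw_cc": 0.844,
    "Pbw_2": 0.487
   },
   "intercept": -37.234,
   "r2": 0.885,
   "adjusted_r2": 0.883
  },
  {
   "cohort": "combined",
   "endpoint": "V25Gy",
   "terms": {
    "Vbw_cc": 0.789,
    "Pbw_1.5": 0.52
   },
   "intercept": -36.586,
   "r2": 0.899,
   "adjusted_r2": 0.896
  },
  {
   "cohort": "combined",
   "endpoint": "V30Gy",
   "terms": {
    "Vbw_cc": 0.71,
    "Pbw_1.5": 0.63,
    "Pb_2": -0.084
   },
   "intercept": -36.859,
   "r2": 0.921,
   "adjusted_r2": 0.918
  },
  {
   "cohort": "combined",
   "endpoint": "V35Gy",
   "terms": {
    "Vbw_cc": 0.653,
    "Pbw_1": 0.628,
    "Pb_0.5": -0.064
   },
   "intercept": -35.393,
   "r2": 0.937,
   "adjusted_r2": 0.934
  },
  {
   "cohort": "combined",
   "endpoint": "V40Gy",
   "terms": {
    "Vbw_cc": 0.604,
    "Pbw_1": 0.623,
    "Pbw_3": -0.084
   },
   "intercept": -30.966,
   "r2": 0.951,
   "adjusted_r2": 0.949
  },
  {
   "cohort": "combined",
   "endpoint": "V45Gy",
   "terms": {
    "Vbw_cc": 0.527,
    "Pbw_0.5": 0.57,
    "Pb_0": -0.041
   },
   "intercept": -28.429,
   "r2": 0.96,
   "adjusted_r2": 0.959
  },
  {
   "cohort": "combined",
   "endpoint": "Dmean",
   "terms": {
    "Pbw_1": 0.337,
    "Pbw_3": 0.082
   },
   "intercept": 11.502,
   "r2": 0.87,
   "adjusted_r2": 0.867
  },
  {
   "cohort": "rectal",
   "endpoint": "V10Gy",
   "terms": {
    "Vbw_cc": 0.916,
    "Pb_3": 0.316
   },
   "intercept": -27.127,
   "r2": 0.926,
   "adjusted_r2": 0.923
  },
  {
   "cohort": "rectal",
   "endpoint": "V15Gy",
   "terms": {
    "Vbw_cc": 0.87,
    "Pb_3": 0.505
   },
   "intercept": -45.715,
   "r2": 0.875,
   "adjusted_r2": 0.87
  },
  {
   "cohort": "rectal",
   "endpoint": "V20Gy",
   "terms": {
    "Vbw_cc": 0.697,
    "Pbw_1": 0.245,
    "Pbw_3": 0.286
   },
   "intercept": -34.129,
   "r2": 0.881,
   "adjusted_r2": 0.873
  },
  {
   "cohort": "rectal",
   "endpoint": "V25Gy",
   "terms": {
    "Vbw_cc": 0.64,
    "Pbw_1.5": 0.517
   },
   "intercept": -30.137,
   "r2": 0.881,
   "adjusted_r2": 0.875
  },
  {
   "cohort": "rectal",
   "endpoint": "V30Gy",
   "terms": {
    "Vbw_cc": 0.551,
    "Pbw_1": 0.551
   },
   "intercept": -26.664,
   "r2": 0.909,
   "adjusted_r2": 0.905
  },
  {
   "cohort": "rectal",
   "endpoint": "V35Gy",
   "terms": {
    "Vbw_cc": 0.538,
    "Pbw_1": 0.555
   },
   "intercept": -28.891,
   "r2": 0.929,
   "adjusted_r2": 0.926
  },
  {
   "cohort": "rectal",
   "endpoint": "V40Gy",
   "terms": {
    "Vbw_cc": 0.496,
    "Pbw_1": 0.644,
    "Pbw_3": -0.113
   },
   "intercept": -24.936,
   "r2": 0.945,
   "adjusted_r2": 0.942
  },
  {
   "cohort": "rectal",
   "endpoint": "V45Gy",
   "terms": {
    "Vbw_cc": 0.48,
    "Pbw_0.5": 0.518
   },
   "intercept": -25.167,
   "r2": 0.953,
   "adjusted_r2": 0.95
  },
  {
   "cohort": "rectal",
   "endpoint": "Dmean",
   "terms": {
    "Pbw_1": 0.321,
    "Pb_3": 0.117
   },
   "intercept": 8.035,
   "r2": 0.898,
   "adjusted_r2": 0.893
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V10Gy",
   "terms": {
    "Vbw_cc": 0.96,
    "Pbw_3": 0.118
   },
   "intercept": -9.526,
   "r2": 0.982,
   "adjusted_r2": 0.981
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V15Gy",
   "terms": {
    "Vbw_cc": 0.931,
    "Pbw_3": 0.328
   },
   "intercept": -29.276,
   "r2": 0.931,
   "adjusted_r2": 0.927
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V20Gy",
   "terms": {
    "Vbw_cc": 0.89,
    "Pbw_3": 0.456
   },
   "intercept": -41.431,
   "r2": 0.905,
   "adjusted_r2": 0.9
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V25Gy",
   "terms": {
    "Vbw_cc": 0.803,
    "Pbw_1.5": 0.424
   },
   "intercept": -29.684,
   "r2": 0.918,
   "adjusted_r2": 0.914
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V30Gy",
   "terms": {
    "Vbw_cc": 0.764,
    "Pbw_1.5": 0.5
   },
   "intercept": -36.014,
   "r2": 0.936,
   "adjusted_r2": 0.932
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V35Gy",
   "terms": {
    "Vbw_cc": 0.519,
    "Pbw_1": 0.706
   },
   "intercept": -33.376,
   "r2": 0.946,
   "adjusted_r2": 0.944
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V40Gy",
   "terms": {
    "Vbw_cc": 0.634,
    "Pbw_1": 0.538
   },
   "intercept": -33.988,
   "r2": 0.956,
   "adjusted_r2": 0.954
  },
  {
   "cohort": "gynecologic",
   "endpoint": "V45Gy",
   "terms": {
    "Vbw_cc": 0.546,
    "Pbw_0.5": 0.531
   },
   "intercept": -28.016,
   "r2": 0.962,
   "adjusted_r2": 0.96
  },
  {
   "cohort": "gynecologic",
   "endpoint": "Dmean",
   "terms": {
    "Pbw_1": 0.327
   },
   "intercept": 20.116,
   "r2": 0.887,
   "adjusted_r2": 0.884
  }
 ]
}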