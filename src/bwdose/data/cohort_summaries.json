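{
 "combined": {
  "n": 94,
  "predictors": {
   "VPTV_cc": {
    "median": 598.5,
    "iqr": [
     488.7,
     762.3
    ]
   },
   "Vbw_cc": {
    "mean": 52.8,
    "sd": 9.4
   },
   "Vbladder_cc": {
    "median": 324.9,
    "iqr": [
     220.1,
     492.0
    ]
   },
   "Pbw_0": {
    "mean": 39.9,
    "sd": 13.3
   },
   "Pbw_0.5": {
    "mean": 48.2,
    "sd": 12.9
   },
   "Pbw_1": {
    "mean": 56.9,
    "sd": 12.6
   },
   "Pbw_1.5": {
    "mean": 64.6,
    "sd": 12.6
   },
   "Pbw_2": {
    "mean": 71.6,
    "sd": 12.4
   },
   "Pbw_2.5": {
    "median": 77.8,
    "iqr": [
     72.2,
     88.0
    ]
   },
   "Pbw_3": {
    "median": 83.6,
    "iqr": [
     78.4,
     92.9
    ]
   },
   "Pb_0": {
    "median": 22.1,
    "iqr": [
     12.9,
     38.3
    ]
   },
   "Pb_0.5": {
    "median": 33.1,
    "iqr": [
     23.5,
     48.2
    ]
   },
   "Pb_1": {
    "mean": 48.9,
    "sd": 16.3
   },
   "Pb_1.5": {
    "mean": 59.9,
    "sd": 16.0
   },
   "Pb_2": {
    "mean": 69.8,
    "sd": 15.2
   },
   "Pb_2.5": {
    "median": 78.6,
    "iqr": [
     66.7,
     90.2
    ]
   },
   "Pb_3": {
    "median": 86.3,
    "iqr": [
     75.9,
     96.5
    ]
   }
  },
  "endpoints": {
   "V10Gy": {
    "mean": 49.8,
    "sd": 9.3
   },
   "V15Gy": {
    "mean": 45.9,
    "sd": 9.9
   },
   "V20Gy": {
    "mean": 42.1,
    "sd": 10.2
   },
   "V25Gy": {
    "mean": 38.6,
    "sd": 10.2
   },
   "V30Gy": {
    "mean": 35.4,
    "sd": 10.1
   },
   "V35Gy": {
    "mean": 32.4,
    "sd": 9.8
   },
   "V40Gy": {
    "mean": 29.3,
    "sd": 9.3
   },
   "V45Gy": {
    "mean": 25.8,
    "sd": 8.6
   },
   "Dmean": {
    "mean": 37.56,
    "sd": 5.44
   }
  }
 },
 "rectal": {
  "n": 49,
  "predictors": {
   "VPTV_cc": {
    "median": 671.9,
    "iqr": [
     572.4,
     806.0
    ]
   },
   "Vbw_cc": {
    "mean": 50.1,
    "sd": 7.9
   },
   "Vbladder_cc": {
    "median": 289.9,
    "iqr": [
     193.5,
     434.9
    ]
   },
   "Pbw_0": {
    "mean": 37.6,
    "sd": 14.0
   },
   "Pbw_0.5": {
    "mean": 45.4,
    "sd": 13.7
   },
   "Pbw_1": {
    "mean": 53.9,
    "sd": 13.7
   },
   "Pbw_1.5": {
    "mean": 61.4,
    "sd": 14.1
   },
   "Pbw_2": {
    "mean": 68.7,
    "sd": 14.3
   },
   "Pbw_2.5": {
    "median": 75.8,
    "iqr": [
     65.4,
     88.3
    ]
   },
   "Pbw_3": {
    "median": 82.3,
    "iqr": [
     72.1,
     93.7
    ]
   },
   "Pb_0": {
    "median": 24.2,
    "iqr": [
     15.2,
     38.7
    ]
   },
   "Pb_0.5": {
    "median": 35.0,
    "iqr": [
     25.8,
     49.1
    ]
   },
   "Pb_1": {
    "mean": 50.1,
    "sd": 16.2
   },
   "Pb_1.5": {
    "mean": 61.2,
    "sd": 16.2
   },
   "Pb_2": {
    "mean": 71.1,
    "sd": 15.8
   },
   "Pb_2.5": {
    "median": 82.6,
    "iqr": [
     67.4,
     92.4
    ]
   },
   "Pb_3": {
    "median": 89.7,
    "iqr": [
     76.3,
     97.3
    ]
   }
  },
  "endpoints": {
   "V10Gy": {
    "mean": 46.1,
    "sd": 7.5
   },
   "V15Gy": {
    "mean": 41.5,
    "sd": 8.4
   },
   "V20Gy": {
    "mean": 37.4,
    "sd": 9.0
   },
   "V25Gy": {
    "mean": 33.7,
    "sd": 9.1
   },
   "V30Gy": {
    "mean": 30.6,
    "sd": 9.1
   },
   "V35Gy": {
    "mean": 28.0,
    "sd": 9.0
   },
   "V40Gy": {
    "mean": 25.3,
    "sd": 8.8
   },
   "V45Gy": {
    "mean": 22.4,
    "sd": 8.4
   },
   "Dmean": {
    "mean": 35.45,
    "sd": 5.99
   }
  }
 },
 "gynecologic": {
  "n": 45,
  "predictors": {
   "VPTV_cc": {
    "median": 549.1,
    "iqr": [
     402.3,
     678.8
    ]
   },
   "Vbw_cc": {
    "mean": 55.6,
    "sd": 10.0
   },
   "Vbladder_cc": {
    "median": 387.2,
    "iqr": [
     283.8,
     526.0
    ]
   },
   "Pbw_0": {
    "mean": 42.5,
    "sd": 12.1
   },
   "Pbw_0.5": {
    "mean": 51.4,
    "sd": 11.3
   },
   "Pbw_1": {
    "mean": 60.3,
    "sd": 10.4
   },
   "Pbw_1.5": {
    "mean": 68.0,
    "sd": 9.7
   },
   "Pbw_2": {
    "mean": 74.8,
    "sd": 9.0
   },
   "Pbw_2.5": {
    "median": 79.4,
    "iqr": [
     74.8,
     87.1
    ]
   },
   "Pbw_3": {
    "median": 85.4,
    "iqr": [
     80.6,
     91.2
    ]
   },
   "Pb_0": {
    "median": 20.1,
    "iqr": [
     12.2,
     38.2
    ]
   },
   "Pb_0.5": {
    "median": 32.3,
    "iqr": [
     21.9,
     47.6
    ]
   },
   "Pb_1": {
    "mean": 47.5,
    "sd": 16.5
   },
   "Pb_1.5": {
    "mean": 58.4,
    "sd": 15.9
   },
   "Pb_2": {
    "mean": 68.4,
    "sd": 14.5
   },
   "Pb_2.5": {
    "median": 76.2,
    "iqr": [
     66.3,
     88.3
    ]
   },
   "Pb_3": {
    "median": 84.3,
    "iqr": [
     75.9,
     93.7
    ]
   }
  },
  "endpoints": {
   "V10Gy": {
    "mean": 54.0,
    "sd": 9.5
   },
   "V15Gy": {
    "mean": 50.7,
    "sd": 9.1
   },
   "V20Gy": {
    "mean": 47.3,
    "sd": 8.9
   },
   "V25Gy": {
    "mean": 43.8,
    "sd": 8.7
   },
   "V30Gy": {
    "mean": 40.5,
    "sd": 8.6
   },
   "V35Gy": {
    "mean": 37.2,
    "sd": 8.3
   },
   "V40Gy": {
    "mean": 33.7,
    "sd": 7.8
   },
   "V45Gy": {
    "mean": 29.6,
    "sd": 7.2
   },
   "Dmean": {
    "mean": 39.85,
    "sd": 3.62
   }
  }
 }
}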