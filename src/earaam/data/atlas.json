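{
 "regions": {
  "helix": [
   0,
   1,
   2,
   3,
   4,
   5,
   6,
   7,
   8,
   9,
   10,
   11,
   12,
   13,
   14,
   15,
   16,
   17,
   18,
   19,
   20,
   21,
   22,
   23,
   24,
   25,
   26,
   27,
   28,
   29,
   30,
   31,
   32,
   33,
   34,
   35,
   55,
   54,
   53,
   52,
   51,
   50,
   49,
   48,
   47,
   46,
   45,
   44,
   43,
   42,
   41,
   40,
   39,
   38,
   37,
   36
  ],
  "fossae helicis": [
   44,
   45,
   46,
   47,
   48,
   49,
   50,
   51,
   52,
   53,
   54,
   55,
   67,
   66,
   65,
   64,
   63,
   62,
   61,
   60,
   59,
   58,
   57,
   56
  ],
  "antihelix": [
   56,
   57,
   58,
   59,
   60,
   61,
   62,
   63,
   64,
   65,
   66,
   67,
   71,
   70,
   69
  ],
  "fossae triangularis auriculae": [
   41,
   42,
   43,
   44,
   56
  ],
  "cymba conchae": [
   74,
   75,
   68,
   69,
   70
  ],
  "cavum conchae": [
   70,
   71,
   72,
   73,
   74
  ],
  "tragus": [
   76,
   77,
   78,
   79
  ],
  "antitragus": [
   72,
   81,
   80
  ],
  "earlobe": [
   "P1",
   "P2",
   "P3",
   "P4",
   "P5",
   "P6",
   "P7",
   "P8",
   "P9"
  ]
 },
 "subareas": {
  "helix": [
   "HX1",
   "HX2",
   "HX3",
   "HX4",
   "HX5",
   "HX6",
   "HX7",
   "HX8",
   "HX9",
   "HX10",
   "HX11",
   "HX12"
  ],
  "antihelix": [
   "AH1",
   "AH2",
   "AH3",
   "AH4",
   "AH5",
   "AH6",
   "AH7",
   "AH8",
   "AH9",
   "AH10",
   "AH11",
   "AH12",
   "AH13"
  ],
  "cymba conchae": [
   "CO1",
   "CO2",
   "CO3",
   "CO4",
   "CO5",
   "CO6"
  ],
  "cavum conchae": [
   "CO7",
   "CO8",
   "CO9",
   "CO10",
   "CO11",
   "CO12",
   "CO13",
   "CO14",
   "CO15",
   "CO16",
   "CO17",
   "CO18"
  ],
  "fossae helicis": [
   "SF1",
   "SF2",
   "SF3",
   "SF4",
   "SF5",
   "SF6"
  ],
  "fossae triangularis auriculae": [
   "TF1",
   "TF2",
   "TF3",
   "TF4",
   "TF5"
  ],
  "tragus": [
   "TG1",
   "TG2",
   "TG3",
   "TG4"
  ],
  "antitragus": [
   "AT1",
   "AT2",
   "AT3",
   "AT4"
  ],
  "earlobe": [
   "LO1",
   "LO2",
   "LO3",
   "LO4",
   "LO5",
   "LO6",
   "LO7",
   "LO8",
   "LO9"
  ]
 }
}
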