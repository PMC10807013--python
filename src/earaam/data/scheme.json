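{
 "point_count": 91,
 "labels": [
  "helix_rim_00",
  "helix_rim_01",
  "helix_rim_02",
  "helix_rim_03",
  "helix_rim_04",
  "helix_rim_05",
  "helix_rim_06",
  "helix_rim_07",
  "helix_rim_08",
  "helix_rim_09",
  "helix_rim_10",
  "helix_rim_11",
  "helix_rim_12",
  "helix_rim_13",
  "helix_rim_14",
  "helix_rim_15",
  "helix_rim_16",
  "helix_rim_17",
  "helix_rim_18",
  "helix_rim_19",
  "helix_rim_20",
  "helix_rim_21",
  "helix_rim_22",
  "helix_rim_23",
  "helix_rim_24",
  "helix_rim_25",
  "helix_rim_26",
  "helix_rim_27",
  "helix_rim_28",
  "helix_rim_29",
  "helix_rim_30",
  "helix_rim_31",
  "helix_rim_32",
  "helix_rim_33",
  "helix_rim_34",
  "helix_rim_35",
  "inner_helix_edge_00",
  "inner_helix_edge_01",
  "inner_helix_edge_02",
  "inner_helix_edge_03",
  "inner_helix_edge_04",
  "inner_helix_edge_05",
  "inner_helix_edge_06",
  "inner_helix_edge_07",
  "inner_helix_edge_08",
  "inner_helix_edge_09",
  "inner_helix_edge_10",
  "inner_helix_edge_11",
  "inner_helix_edge_12",
  "inner_helix_edge_13",
  "inner_helix_edge_14",
  "inner_helix_edge_15",
  "inner_helix_edge_16",
  "inner_helix_edge_17",
  "inner_helix_edge_18",
  "inner_helix_edge_19",
  "antihelix_ridge_00",
  "antihelix_ridge_01",
  "antihelix_ridge_02",
  "antihelix_ridge_03",
  "antihelix_ridge_04",
  "antihelix_ridge_05",
  "antihelix_ridge_06",
  "antihelix_ridge_07",
  "antihelix_ridge_08",
  "antihelix_ridge_09",
  "antihelix_ridge_10",
  "antihelix_ridge_11",
  "concha_rim_00",
  "concha_rim_01",
  "concha_rim_02",
  "concha_rim_03",
  "concha_rim_04",
  "concha_rim_05",
  "concha_rim_06",
  "concha_rim_07",
  "tragus_0",
  "tragus_1",
  "tragus_2",
  "tragus_3",
  "antitragus_0",
  "antitragus_1",
  "earlobe_contour_0",
  "earlobe_contour_1",
  "earlobe_contour_2",
  "earlobe_contour_3",
  "earlobe_contour_4",
  "earlobe_contour_5",
  "earlobe_contour_6",
  "earlobe_contour_7",
  "earlobe_contour_8"
 ],
 "earlobe_contour_indices": [
  82,
  83,
  84,
  85,
  86,
  87,
  88,
  89,
  90
 ],
 "group_map": {
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
   36,
   37,
   38,
   39,
   40,
   41,
   42,
   43,
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
   55
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
   67
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
   69,
   70,
   71
  ],
  "fossae triangularis auriculae": [
   41,
   42,
   43,
   44,
   56,
   57
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
   80,
   81
  ],
  "earlobe": [
   82,
   83,
   84,
   85,
   86,
   87,
   88,
   89,
   90
  ]
 }
}
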