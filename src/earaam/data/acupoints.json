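{
 "acupoints": [
  {
   "name": "Lumbosacral vertebrae",
   "kind": "area",
   "region": "antihelix",
   "rel": [
    0.55,
    0.35
   ],
   "rel_size": 0.22
  },
  {
   "name": "Adrenal gland",
   "kind": "point",
   "region": "tragus",
   "rel": [
    0.5,
    0.75
   ]
  },
  {
   "name": "Shenmen",
   "kind": "area",
   "region": "fossae triangularis auriculae",
   "rel": [
    0.65,
    0.4
   ],
   "rel_size": 0.3
  },
  {
   "name": "Heart",
   "kind": "area",
   "region": "cavum conchae",
   "rel": [
    0.5,
    0.45
   ],
   "rel_size": 0.3
  },
  {
   "name": "Kidney",
   "kind": "area",
   "region": "cymba conchae",
   "rel": [
    0.45,
    0.5
   ],
   "rel_size": 0.3
  },
  {
   "name": "Stomach",
   "kind": "area",
   "region": "cymba conchae",
   "rel": [
    0.6,
    0.75
   ],
   "rel_size": 0.25
  },
  {
   "name": "Ear apex",
   "kind": "point",
   "region": "helix",
   "rel": [
    0.5,
    0.05
   ]
  },
  {
   "name": "Eye",
   "kind": "area",
   "region": "earlobe",
   "subarea": 5,
   "rel_size": 0.3
  },
  {
   "name": "Anterior ear lobe",
   "kind": "point",
   "region": "earlobe",
   "subarea": 4
  }
 ]
}
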