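{
 "description": "Simplified nearest-neighbour free-energy model (37 C, kcal/mol) for nested RNA secondary structure. Stacking table seeded from published Turner-style values; loop initiation penalties indexed by size with Jacobson-Stockmayer extrapolation beyond the tabulated range. Users may substitute full Turner parameters by editing this file.",
 "min_loop": 3,
 "max_interior": 30,
 "multiloop_init": 3.4,
 "allowed_pairs": [
  "AU",
  "UA",
  "GC",
  "CG",
  "GU",
  "UG"
 ],
 "stack": {
  "AU": {
   "AU": -0.93,
   "UA": -1.1,
   "GC": -2.08,
   "CG": -2.24,
   "GU": -0.55,
   "UG": -1.36
  },
  "UA": {
   "AU": -1.33,
   "UA": -0.93,
   "GC": -2.11,
   "CG": -2.35,
   "GU": -1.0,
   "UG": -1.27
  },
  "GC": {
   "AU": -2.35,
   "UA": -2.24,
   "GC": -3.26,
   "CG": -3.42,
   "GU": -1.53,
   "UG": -2.51
  },
  "CG": {
   "AU": -2.11,
   "UA": -2.08,
   "GC": -2.36,
   "CG": -3.26,
   "GU": -1.41,
   "UG": -2.11
  },
  "GU": {
   "AU": -1.27,
   "UA": -1.36,
   "GC": -2.11,
   "CG": -2.51,
   "GU": -0.5,
   "UG": 0.0
  },
  "UG": {
   "AU": -1.0,
   "UA": -0.55,
   "GC": -1.41,
   "CG": -1.53,
   "GU": 0.0,
   "UG": -0.5
  }
 },
 "hairpin": {
  "3": 5.4,
  "4": 5.6,
  "5": 5.7,
  "6": 5.4,
  "7": 6.0,
  "8": 5.5,
  "9": 6.4
 },
 "bulge": {
  "1": 3.8,
  "2": 2.8,
  "3": 3.2,
  "4": 3.6,
  "5": 4.0,
  "6": 4.4
 },
 "internal": {
  "2": 1.7,
  "3": 1.8,
  "4": 2.0,
  "5": 2.2,
  "6": 2.5
 },
 "extrapolation": {
  "coefficient": 1.75,
  "RT": 0.616
 }
}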