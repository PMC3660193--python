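{
 "maps": {
  "f2": {
   "length_cM": 311.44,
   "n_lg": 3,
   "n_markers": 63
  },
  "g2f": {
   "length_cM": 218.52,
   "n_lg": 3,
   "n_markers": 37
  },
  "g2m": {
   "length_cM": 256.11,
   "n_lg": 3,
   "n_markers": 40
  }
 },
 "n_distorted_f2": 6,
 "n_sdr_candidates": 1,
 "n_sdr_validated": 1,
 "sdr": [
  {
   "deficient_origin": "grandparent_hap1",
   "lg": "LG2",
   "stage": "postzygotic",
   "status": "validated"
  }
 ]
}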