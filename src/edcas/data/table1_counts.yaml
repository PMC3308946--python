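# Published per-group classified-read counts for the 32 cassette isoforms.
# Keys are edited-site sets ('-' = unedited); values are lean / ob/ob counts.
counts:
  ABD: {lean: 3607, obob: 3429}
  AD: {lean: 283, obob: 253}
  AB: {lean: 1871, obob: 2175}
  A: {lean: 857, obob: 962}
  ABCD: {lean: 1278, obob: 1094}
  ACD: {lean: 60, obob: 63}
  -: {lean: 720, obob: 588}
  ABECD: {lean: 37, obob: 25}
  AECD: {lean: 11, obob: 6}
  ABC: {lean: 850, obob: 997}
  AC: {lean: 119, obob: 114}
  B: {lean: 45, obob: 48}
  E: {lean: 19, obob: 12}
  C: {lean: 67, obob: 61}
  D: {lean: 354, obob: 203}
  ABED: {lean: 98, obob: 77}
  AED: {lean: 16, obob: 9}
  ABE: {lean: 84, obob: 70}
  AE: {lean: 26, obob: 24}
  CD: {lean: 30, obob: 52}
  BD: {lean: 54, obob: 41}
  ABEC: {lean: 30, obob: 29}
  AEC: {lean: 31, obob: 21}
  ECD: {lean: 1, obob: 10}
  BC: {lean: 6, obob: 9}
  EC: {lean: 6, obob: 2}
  ED: {lean: 14, obob: 3}
  BE: {lean: 0, obob: 0}
  BEC: {lean: 0, obob: 0}
  BED: {lean: 0, obob: 0}
  BCD: {lean: 0, obob: 0}
  BECD: {lean: 0, obob: 0}
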