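# BIS-11 scoring key (Patton, Stanford & Barratt, 1995).
# 30 items, 4-point Likert responses (1..4).  Items listed under `reverse`
# are reverse-scored (score = 5 - response) before summation.  Each item
# belongs to exactly one second-order subscale.
subscales:
  attentional: [5, 6, 9, 11, 20, 24, 26, 28]
  motor: [2, 3, 4, 16, 17, 19, 21, 22, 23, 25, 30]
  non_planning: [1, 7, 8, 10, 12, 13, 14, 15, 18, 27, 29]
reverse: [1, 7, 8, 9, 10, 12, 13, 15, 20, 29, 30]
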