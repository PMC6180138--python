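# Item metadata for the four self-report instruments used by the pipeline.
#
# binarize_cut c: an ordinary item maps to 1 ("presence/empathic/expressive")
# iff score >= c; a reversed item maps to 1 iff score < c (the exact
# complement, matching each instrument's published dichotomization ranges).
instruments:
  DASS21:
    label: "DASS-21"
    n_items: 21
    scale_min: 0
    scale_max: 3
    binarize_cut: 1          # absence (0) vs presence (1-3)
    reversed_items: []
    reverse_score_totals: false
    subscales:
      depression: [3, 5, 10, 13, 16, 17, 21]
      anxiety: [2, 4, 7, 9, 15, 19, 20]
      stress: [1, 6, 8, 11, 12, 14, 18]
  EQ_SHORT:
    label: "EQ-short"
    n_items: 11
    scale_min: 0
    scale_max: 3
    binarize_cut: 2          # no empathy (0-1) vs empathic (2-3)
    reversed_items: []
    reverse_score_totals: false
    # Korean 11-item short form: positions 1..11 correspond to these
    # source-item numbers of the 22-item EQ short form.
    source_items: [1, 6, 9, 10, 13, 14, 16, 18, 19, 20, 21]
  JSE_S:
    label: "JSE-S"
    n_items: 20
    scale_min: 1
    scale_max: 7
    binarize_cut: 4          # ordinary: empathic 4-7; reversed: empathic 1-3
    reversed_items: [1, 3, 6, 7, 8, 11, 12, 14]
    reverse_score_totals: true
  EES:
    label: "EES"
    n_items: 17
    scale_min: 1
    scale_max: 5
    binarize_cut: 3          # ordinary: expressive 3-5; reversed: expressive 1-2
    reversed_items: [2, 3, 4, 7, 9, 10, 11, 12, 15, 16, 17]
    reverse_score_totals: true
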