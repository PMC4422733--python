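# Presence thresholds for domain PSSM scoring, in mean log-odds bits per
# column of the best window.  Calibrated against shuffled-protein and random
# protein nulls (99th percentile plus margin) while retaining the weakest
# planted family instances; see docs/methods.md.
thresholds:
  gstn: 0.08
  gstc: 0.10
  thx: 0.055
  mapeg: 0.15
# minimum number of overlapping PSSM columns in a scored window
min_cols: 50
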