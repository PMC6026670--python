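# Default synthetic end-to-end run: simulated boreal landscape and
# bryophyte community, full DTW threshold suite, mixed-model fits with
# AICc threshold selection, then ISA / PERMANOVA / NMDS per forest type
# at the selected threshold.
seed: 20260924
outdir: runs/default
landscape:
  n_rows: 120
  n_cols: 120
  cell_size: 10.0
community: {}
thresholds: [0.5, 1, 2, 4, 8, 12, 16]
generating_lambda: 4.0
n_perm: 199
nmds_restarts: 5
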