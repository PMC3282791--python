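# Mosaic mono-allelic deletion in ~80% of cells: CN 1.2, bands 0.17/0.83.
n_samples: 1
markers_per_chrom: 1000
chrom_lengths: {1: 50000000, 2: 50000000}
seed: 4
events:
  - {sample: S000, chrom: 1, start: 1, end: 25000000, b_count: 0, n_copies: 1, p_aberrant: 0.80}
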