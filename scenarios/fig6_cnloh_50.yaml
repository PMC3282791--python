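# Copy-neutral LOH in ~50% of cells: CN 2.0, bands 0.25/0.75 on one whole
# chromosome; the other chromosome stays normal (CN 2, single band at 0.5).
n_samples: 1
markers_per_chrom: 1000
chrom_lengths: {1: 50000000, 2: 50000000}
seed: 6
events:
  - {sample: S000, chrom: 1, start: 1, end: 50000000, b_count: 2, n_copies: 2, p_aberrant: 0.50}
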