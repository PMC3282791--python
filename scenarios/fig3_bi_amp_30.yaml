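# Mosaic bi-allelic amplification (AABB) in ~30% of cells: CN 2.6, unsplit BAF.
n_samples: 1
markers_per_chrom: 1000
chrom_lengths: {1: 50000000, 2: 50000000}
seed: 3
events:
  - {sample: S000, chrom: 2, start: 25000001, end: 50000000, b_count: 2, n_copies: 4, p_aberrant: 0.30}
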