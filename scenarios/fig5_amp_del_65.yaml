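# Paired arm events in the same sample, both at ~65% aberrant cells:
# mono-allelic deletion (CN 1.35) and mono-allelic amplification (CN 2.65).
n_samples: 1
markers_per_chrom: 1000
chrom_lengths: {1: 50000000, 2: 50000000}
seed: 5
events:
  - {sample: S000, chrom: 1, start: 1, end: 25000000, b_count: 0, n_copies: 1, p_aberrant: 0.65}
  - {sample: S000, chrom: 2, start: 25000001, end: 50000000, b_count: 2, n_copies: 3, p_aberrant: 0.65}
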