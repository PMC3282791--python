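# Mosaic isotrisomy: mono-allelic amplification superimposed on cnLOH (AAA
# clone), CN amplified with a large heterozygote-pane split.
n_samples: 1
markers_per_chrom: 1000
chrom_lengths: {1: 50000000, 2: 50000000}
seed: 7
events:
  - {sample: S000, chrom: 2, start: 25000001, end: 50000000, b_count: 3, n_copies: 3, p_aberrant: 0.60}
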