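# Demo run: a 1-Mb two-chromosome synthetic genome (100 x 10-kb windows,
# ~10k CG dyads) so the whole pipeline finishes in well under a minute.
seed: 1
outdir: oometh_demo
simulation:
  genome_spec: [["chr1", 600000], ["chr2", 400000]]
  noncg_density: 40.0
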