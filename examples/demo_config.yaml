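# Demo pipeline run: simulate an RB-Tn-Seq time course and process it end to end.
#   tntrace run-all examples/demo_config.yaml
mode: rbtnseq
seed: 5
outdir: tntrace_demo
genome_length: 20000
n_genes: 10
n_founders: 2
insertions_per_founder: 1
n_pairs: 1500
pcr_duplication: 1.0
error_rate: 0.0
selection: true        # simulate a selected end point (enables diff + lineage stages)
gain_fraction: 0.6
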