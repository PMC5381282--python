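# Full-pipeline config for `limerad run --config run_config.yaml`.
# Generate the input first:
#   limerad simulate --sites 40000 --seed 7 --out sim.fasta
alignment: sim.fasta
format: fasta
# partition: clusters.yaml   # omit to use the shipped eight-accession grouping
out_dir: limerad_out
n_loci: 40000
read_length: 41
seed: 7
match_categories: [E, G]
subpattern_categories: [E, G]
tree: true
tree_metric: mismatch
bootstrap: 100
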