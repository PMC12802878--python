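# Example run configuration.
# Generate the demonstration proteome first:
#   proteasim make-fixture --n-proteins 300 --small-fraction 0.3 --seed 7 \
#       --output demo/proteome.fasta
fasta: demo/proteome.fasta
output_dir: demo/out
master_seed: 11
n_samples: 5
max_mc: 5

groups:
  - {label: small, min_length: 1, max_length: 70}
  - {label: large, min_length: 71, max_length: null}

abundance:
  distribution: lognormal
  location: 0.0
  scale: 2.0
  undetectable_fraction: 0.45

proteases:
  - {name: trypsin, peptides: 1000}
  - {name: lys-c, peptides: 1000}
  - {name: lysarginase, peptides: 1000}

control: [trypsin]
weights: {prot: 1.0, pep: 1.0, cov: 1.0}

filter:
  min_length: 6
  max_length: 45
  min_mass: 400.0
  max_mass: 6000.0

detectability:
  source: uniform

require_unique: true
with_replacement: false
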