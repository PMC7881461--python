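reference: examples/locus.fasta
targets: examples/target.vcf
known: examples/known.vcf
out: scratch/demo_run
seed: 7
true_aaf: 0.05
depth_per_amplicon: 300
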