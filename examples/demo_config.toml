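# Demo pipeline configuration: a small end-to-end qXR-Seq run.
# Execute with:  xrquant run-all --config examples/demo_config.toml --out demo_out
seed = 0
species_preset = "worm"
sample_species = "worm"
spike_species = "fly"
dilutions = [1.0, 0.1, 0.01, 0.001]
spike_reads = 800
mutant_relative = 0.01
background_relative = 0.001

[sample_sim]
genome_sizes = {chr1 = 80000, chrM = 6000}
n_genes = 15
gene_length_range = [1200, 3000]
n_reads = 4000

[spike_sim]
genome_sizes = {chrS = 30000}
n_genes = 5
n_reads = 2500
mito_fraction = 0.0
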