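# isochrom demo: 200-gene synthetic two-condition run
[simulation]
n_genes = 200
n_replicates_per_condition = 3
seed = 20240501
planted_de_fraction = 0.1
de_log2_effect = 2.0
psi_wildtype = 0.02
psi_transgenic = 0.25
nb_dispersion = 0.1
coordination_fraction = 0.1
coordination_log2_effect = 2.0
atac_fold = 4.0
junction_depth = 2000
motif_insertion_rate = 0.05
sequence_length = 200000
gc_content = 0.42

[paths]
outdir = isochrom_demo_out

[de]
p_threshold = 0.05
lfc_threshold = 0.5

[chromatin]
window_bp = 2000
fold_threshold = 2.0

[integration]
iterations = 4000
burnin = 1000
chains = 2
hdi_mass = 0.95
significance = 0.999
grouping = per-sample

[motif]
p_threshold = 1e-4
q_threshold = 0.01
discretization_bins = 10000

[enrichment]
n_tfs = 20
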