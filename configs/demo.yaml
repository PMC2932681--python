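# Demo configuration: a small synthetic study that exercises every stage.
# Values mirror the package defaults; edit and pass via `lfcna run --config`.
seed: 0
n_genes: 1500
clustering: 1.0
n_samples_a: 120
n_samples_b: 80
n_clones: 400
noise_sd: 0.5
clone_noise_sd: 0.2
score_noise_sd: 0.2
cis_segments:
  - [chr8, 2000000, 12000000]
  - [chr17, 35000000, 45000000]
trans_segments:
  - [chr12, 65000000, 75000000]
n_neutral: 2
n_members: 25
experiment_genes: 300
group_sizes: [12, 12, 12]
affected_fraction: 0.1
effect_size: 2.0
signature_iters: 1500
signature_burn_in: 300
factor_iters: 600
factor_burn_in: 200
kernel_fraction: 0.05
ler_permutations: 500
alpha_ler: 0.002
alpha_assoc: 0.01
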