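# Laptop-scale end-to-end demo: synthetic 400-subject cohort, two planted
# covariation modes, one lateralized subnucleus pair, 12 phenotypes.
out_dir: plastcov_demo_run
seed: 7
n_subjects: 400
n_modes: 2
mode_strengths: [4.0, 2.0]
noise_sd: 1.0
confound_effects:
  bmi: 0.3
  head_size: 0.3
asymmetry_mode_1: [0.5, 0.0, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0, 0.0]
n_phenotypes: 12
phenotype_effect: 0.5
n_pls_modes: 2
# minimum attainable permutation p is 1/(n_perm+1); 399 permutations allow
# p = 0.0025 to clear the strict p < 0.005 retention gate
n_perm: 399
n_boot: 100
alpha: 0.05
fdr_q: 0.05
perm_alpha: 0.005
age_bins: 6
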