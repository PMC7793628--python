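# Production run settings for the gnathostome fossil analysis.
#
# These reproduce the published analysis settings verbatim: 800 million
# generations sampled every 400,000 with 10% burn-in (2001 logged samples,
# 1801 retained) across four independent runs, homoplasy partitioning at
# concavity k = 10, and the prior set listed below.  The character matrix,
# homology-block column declarations, fossil-site age table and the taxon
# membership of the monophyly constraints accompany the dataset itself
# (supplementary data of the study); fill in `matrix_path`, `blocks`,
# `sites` and `constraints` from those files before launching.
#
# At these settings a run is cluster-scale; desk-scale analyses should
# shorten the chain, not change the priors.

matrix_path: null            # NEXUS matrix (fixed + homology-block columns)
blocks: {}                   # e.g. {jaw_bones: [[490, ...], [508, ...]]}
sites: []                    # fossil sites: name, min_age, max_age, taxa
constraints: []              # gnathostomes; gnathostomes+osteostracans;
                             # polybranchiaspids (taxon lists from the dataset)
focal_clade: []              # apomorphy-defined gnathostomes (= first constraint)

chain_length: 800000000
sample_every: 400000
burnin_fraction: 0.1
n_runs: 4
seed: 1

mkv: false                   # plain Mk, no variable-character conditioning
rho: 0.0                     # all-fossil dataset: no extant sampling
concavity: 10.0              # implied-weights concavity constant k

priors:
  birth_real_space_mean: 0.14   # lognormal birth prior, mean in real space
  birth_sigma: 0.9              # log-space standard deviation
  birth_sigma_real_space: false
  death_mean: 0.1               # exponential prior on extinction rate
  sampling_mean: 0.1            # exponential prior on fossil-sampling rate
  clock_log_mean: -5.5          # lognormal clock-rate prior (log space)
  clock_sigma: 2.0
  clock_sd_mean: 1.0            # exponential prior on clock stdev
  rate_prior_mean: 1.0          # normal prior on partition rates
  rate_prior_sd: 2.0
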