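# Meadow-style workflow: continuous stressor intensity (e.g. stock nights),
# quartile strata on predicted suitability, point-biserial correlation of
# occupancy with log(1 + use), suitability-weighted within-stratum
# permutation, equal-weight mean across strata.
n_strata: 4
statistic: point_biserial
aggregation: mean
weighted_permutation: true
log1p: true
n_permutations: 10000
p_value_rule: raw_proportion
seed: 0
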