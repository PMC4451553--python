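# Lake-style workflow: binary stressor presence (e.g. introduced fish),
# quintile strata on predicted suitability, difference-in-means statistic,
# unweighted within-stratum permutation, equal-weight mean across strata.
n_strata: 5
statistic: mean_difference
aggregation: mean
weighted_permutation: false
log1p: false
n_permutations: 10000
p_value_rule: raw_proportion
seed: 0
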