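# Control (untreated tap-water irrigation) cohort preset.
# Targets: stage deaths (1, 0, 1, 1) of 50, 41 females / 6 males among the
# 47 adults, mean fecundity 49.93 eggs per female, published stage-duration
# and adult-longevity means.  Death probabilities are per stage entrant
# (1/50, 0/49, 1/49, 1/48).
name: control
n: 50
seed: 1
stage_death_probs: [0.02, 0.0, 0.02040816326530612, 0.020833333333333332]
stage_duration_means: [8.02, 3.12, 2.06, 3.06]
stage_duration_sds: [0.8, 0.5, 0.5, 0.6]
p_female: 0.8723404255319149          # 41/47
apop_mean: 1.48
apop_sd: 0.5
female_longevity_mean: 17.29
female_longevity_sd: 5.0
male_longevity_mean: 14.16
male_longevity_sd: 5.0
fecundity_target: 49.93
fecundity_peak_day: 5
fecundity_end_day: 26
fecundity_dispersion: null
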