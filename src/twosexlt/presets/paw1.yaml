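# PAW1 (6.0 min plasma-activated water irrigation) cohort preset.
# Targets: bracketed stage deaths (10, 7, 0, 4) of 50 (42% immature
# mortality; the published 52% headline conflicts with the bracketed
# counts and the preset follows the counts), 21 females / 8 males among
# the 29 adults, mean fecundity 37.14 eggs per female.  Death
# probabilities are per stage entrant (10/50, 7/40, 0/33, 4/33).
name: paw1
n: 50
seed: 1
stage_death_probs: [0.2, 0.175, 0.0, 0.12121212121212122]
stage_duration_means: [8.0, 3.12, 2.21, 3.44]
stage_duration_sds: [0.8, 0.5, 0.5, 0.6]
p_female: 0.7241379310344828          # 21/29
apop_mean: 1.57
apop_sd: 0.5
female_longevity_mean: 14.76
female_longevity_sd: 5.0
male_longevity_mean: 9.12
male_longevity_sd: 3.0
fecundity_target: 37.14
fecundity_peak_day: 5
fecundity_end_day: 22
fecundity_dispersion: null
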