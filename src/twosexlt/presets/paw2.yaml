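# PAW2 (9.4 min plasma-activated water irrigation) cohort preset.
# Targets: stage deaths (6, 6, 1, 0) of 50 (26% immature mortality),
# 25 females / 12 males among the 37 adults, mean fecundity 32.52 eggs
# per female.  Death probabilities are per stage entrant
# (6/50, 6/44, 1/38, 0/37).
name: paw2
n: 50
seed: 1
stage_death_probs: [0.12, 0.13636363636363635, 0.02631578947368421, 0.0]
stage_duration_means: [8.1, 3.1, 2.4, 3.24]
stage_duration_sds: [0.8, 0.5, 0.5, 0.6]
p_female: 0.6756756756756757          # 25/37
apop_mean: 1.66
apop_sd: 0.5
female_longevity_mean: 13.6
female_longevity_sd: 5.0
male_longevity_mean: 8.0
male_longevity_sd: 3.0
fecundity_target: 32.52
fecundity_peak_day: 5
fecundity_end_day: 20
fecundity_dispersion: null
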