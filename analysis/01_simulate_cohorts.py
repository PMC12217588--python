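#!/usr/bin/env python
"""Generate one synthetic 50-individual cohort per treatment preset.

The three presets (control, paw1, paw2) emulate spider-mite cohorts on
untreated and plasma-activated-water-irrigated tomato plants: they target
the published stage-death counts, sex ratios, stage durations, adult
longevities, and mean fecundities.  Writes one cohort CSV per treatment
under results/cohorts/ and prints the realized composition.
"""

import argparse
from pathlib import Path

from twosexlt import PRESET_NAMES, generate_cohort, load_preset, stage_summaries, write_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=50)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohorts"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for offset, name in enumerate(PRESET_NAMES):
        cohort = generate_cohort(load_preset(name), n=args.n, seed=args.seed + offset)
        path = args.outdir / f"{name}.csv"
        write_cohort(cohort, path)
        ss = stage_summaries(cohort)
        print(
            f"{name}: n01 = {ss.n01}, females = {ss.n_female}, males = {ss.n_male}, "
            f"immature deaths = {ss.n_immature_dead} "
            f"(mortality {ss.immature_mortality:.2f}) -> {path}"
        )


if __name__ == "__main__":
    main()
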