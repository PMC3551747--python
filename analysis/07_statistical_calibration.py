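"""Calibration and power of the survey analysis by simulation.

Two checks of the end-to-end statistical machinery: (i) type-I error — under
a null survey design in which host species and symbiont ribospecies are
independent (hosts lumped so every expected cell is large enough for the
chi-square approximation), the G-test should reject at the nominal 5% rate;
(ii) power — the full simulate → trace → call → cluster → G-test pipeline
should recover the planted date × ribospecies shift of the study design
essentially always, given its very large effect (printed G ≈ 57 on df 4).
"""

import argparse

import numpy as np

from osedax16s.association_stats import ContingencyTable, g_test
from osedax16s.pipeline import run_survey_analysis
from osedax16s.synthetic_data import (
    SimulationConfig,
    SurveyDesign,
    generate_survey,
    study_survey_design,
)


def type_one_error(seed: int, n_reps: int) -> float:
    design = SurveyDesign(
        dates=("Oct-06", "Jan-07", "Aug-07", "Dec-07", "Mar-09"),
        worms_per_date=(32, 19, 35, 34, 33),
        ribospecies_probs=(0.5, 0.5),
        host_probs={
            "O. rubiplumus": 67 / 153,
            "O. frankpressi": 34 / 153,
            "other": 52 / 153,
        },
    )
    rejections = tested = 0
    for rep in range(n_reps):
        survey = generate_survey(
            SimulationConfig(seed=seed + rep, survey=design, strains_per_worm=(1, 1))
        )
        counts: dict[tuple[str, str], int] = {}
        for worm in survey.worms:
            key = (worm.host_species, survey.true_species[worm.worm_id])
            counts[key] = counts.get(key, 0) + 1
        hosts = sorted({h for h, _ in counts})
        species = sorted({s for _, s in counts})
        observed = np.array(
            [[counts.get((h, s), 0) for s in species] for h in hosts]
        )
        if (observed.sum(0) == 0).any() or (observed.sum(1) == 0).any():
            continue
        tested += 1
        rejections += g_test(
            ContingencyTable.from_counts(observed, hosts, species)
        ).p_value < 0.05
    return rejections / tested


def power(seed: int, n_reps: int) -> float:
    hits = 0
    for rep in range(n_reps):
        analysis = run_survey_analysis(
            SimulationConfig(survey=study_survey_design()), seed=seed + rep
        )
        hits += analysis.gtest.p_value < 0.05
    return hits / n_reps


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--null-reps", type=int, default=1000)
    parser.add_argument("--power-reps", type=int, default=40)
    args = parser.parse_args()

    rate = type_one_error(args.seed, args.null_reps)
    half_width = 1.96 * np.sqrt(0.05 * 0.95 / args.null_reps)
    print(
        f"type-I error over {args.null_reps} null surveys: {rate:.3f} "
        f"(95% interval around 0.05: ±{half_width:.3f})"
    )
    pw = power(args.seed + args.null_reps, args.power_reps)
    print(
        f"power to detect the planted temporal ribospecies shift over "
        f"{args.power_reps} surveys: {pw:.2f}"
    )


if __name__ == "__main__":
    main()
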