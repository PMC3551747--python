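"""Call consensus sequences from simulated traces and characterise the
mixed-infection detection limit.

Re-simulates the survey of 01, renders each worm's strain mixture as a
peak-height trace, applies the half-height calling rule, and compares how
many mixed infections survive direct-sequencing detection.  Also runs a
noiseless and a noisy dilution series, reports the analytic detection
threshold, and sketches how the amplification-noise scale σ moves the
detection onset relative to the published empirical series (which detected
minorities at 30:70, and in one mixture already at 20:80).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from osedax16s.datasets import load_dilution_calls
from osedax16s.synthetic_data import SimulationConfig, generate_survey, trace_heights
from osedax16s.trace_calling import (
    call_consensus_heights,
    detection_probability,
    detection_threshold,
    simulate_dilution_series,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    config = SimulationConfig(seed=args.seed)
    survey = generate_survey(config)
    rng = np.random.default_rng(args.seed + 1)

    rows = []
    for worm in survey.worms:
        mixture = survey.mixtures[worm.worm_id]
        heights = trace_heights(mixture, config.efficiency_sd, rng)
        call = call_consensus_heights(heights, id=worm.worm_id)
        rows.append(
            {
                "worm_id": worm.worm_id,
                "true_strains": len(mixture),
                "called_mixed": call.mixed,
                "ambiguous_sites": len(call.ambiguous_positions),
                "consensus": call.seq.seq,
            }
        )
    calls = pd.DataFrame(rows)
    calls.to_csv(args.outdir / "consensus_calls.tsv", sep="\t", index=False)

    truly_mixed = calls["true_strains"] >= 2
    detected = calls["called_mixed"]
    print(
        f"{truly_mixed.sum()}/{len(calls)} worms truly carry ≥2 strains; "
        f"direct-sequencing calls flag {detected.sum()} "
        f"({100 * detected.sum() / truly_mixed.sum():.0f}% of the mixed ones)"
    )

    threshold = detection_threshold(0.5)
    print(f"analytic minority detection limit at half-height calling: {threshold:.3f}")
    uniform = detection_probability(stats.uniform(0, 0.5), threshold)
    print(
        "with minority fractions uniform on (0, 0.5): detection probability "
        f"{uniform.probability:.3f}, multiple-infection frequency underestimated "
        f"{uniform.underestimation_factor:.1f}-fold"
    )

    a, b = survey.pool.records[0], survey.pool.records[1]
    noiseless = simulate_dilution_series(a, b, efficiency_sd=0.0, seed=args.seed)
    window = noiseless.ambiguous_ratios(noiseless.snp_positions[0])
    print(f"noiseless 10%-grid dilution series detects both templates at {window}")

    # σ demo: how amplification noise moves the detection onset at 30:70/20:80
    empirical = load_dilution_calls()
    onsets = {
        name: min(result.detected_ratios(result.snp_positions[0]))
        for name, result in empirical.items()
    }
    print(f"empirical detection onsets (fraction of first template): {onsets}")
    demo_rows = []
    for sigma in (0.0, 0.2, 0.4, 0.6):
        series = simulate_dilution_series(
            a, b, replicates=200, efficiency_sd=sigma, seed=args.seed + 2
        )
        pos = series.snp_positions[0]
        col = series.calls[pos]
        for ratio in (0.2, 0.3, 0.4):
            rate = (col.loc[ratio].isin(["R", "Y", "S", "W", "K", "M"])).mean()
            demo_rows.append({"sigma": sigma, "ratio": ratio, "ambiguity_rate": rate})
    demo = pd.DataFrame(demo_rows).pivot(
        index="sigma", columns="ratio", values="ambiguity_rate"
    )
    demo.to_csv(args.outdir / "dilution_noise_demo.tsv", sep="\t")
    print("per-σ ambiguity-call rates at minority 20/30/40%:")
    print(demo.to_string())
    print(
        "larger σ makes detection probabilistic around the 1/3 limit — "
        "occasional detection at 20:80, occasional loss at 40:60, as in the "
        "published series"
    )


if __name__ == "__main__":
    main()
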