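"""End-to-end synthetic pipeline: survey → traces → calling → clustering → G-test.

This glues the per-stage modules into the full analysis a survey would
undergo: every simulated worm's strain mixture is rendered as a peak-height
trace, a consensus is called with the half-height rule (so minority strains
below the detection limit vanish, as in real direct sequencing), the called
consensus sequences are clustered into ribospecies at 3% divergence, and the
date×ribospecies contingency is tested for independence with the G-test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .association_stats import ContingencyTable, GTestResult, g_test
from .core_io import SequenceRecord
from .diversity import RibospeciesClustering, cluster_ribospecies
from .synthetic_data import SimulationConfig, SurveyResult, generate_survey, trace_heights
from .trace_calling import call_consensus_heights

__all__ = ["SurveyAnalysis", "run_survey_analysis"]


@dataclass(frozen=True)
class SurveyAnalysis:
    """Everything the pipeline produced for one simulated survey."""

    survey: SurveyResult
    consensus: Mapping[str, SequenceRecord]
    clustering: RibospeciesClustering
    contingency: ContingencyTable
    gtest: GTestResult


def run_survey_analysis(config: SimulationConfig, seed: int | None = None) -> SurveyAnalysis:
    """Simulate a survey and push it through calling, clustering and testing.

    ``seed`` overrides ``config.seed`` when given.  The contingency table
    crosses sampling date with the ribospecies cluster of each worm's called
    consensus; worms are assigned the cluster label of their own consensus
    sequence, so undetected minority strains influence nothing downstream —
    exactly the bias direct sequencing has.
    """
    if seed is not None:
        config = replace(config, seed=int(seed))
    survey = generate_survey(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))

    consensus: dict[str, SequenceRecord] = {}
    for worm in survey.worms:
        heights = trace_heights(
            survey.mixtures[worm.worm_id], config.efficiency_sd, rng
        )
        consensus[worm.worm_id] = call_consensus_heights(
            heights, id=worm.worm_id
        ).seq

    clustering = cluster_ribospecies(list(consensus.values()), threshold=0.03)
    counts: dict[tuple[str, str], int] = {}
    for worm in survey.worms:
        key = (worm.date, clustering.assignment[worm.worm_id])
        counts[key] = counts.get(key, 0) + 1
    dates = list(dict.fromkeys(w.date for w in survey.worms))
    groups = sorted(set(clustering.assignment.values()))
    observed = pd.DataFrame(
        [[counts.get((d, g), 0) for g in groups] for d in dates],
        index=dates,
        columns=groups,
        dtype=float,
    )
    table = ContingencyTable(observed=observed)
    return SurveyAnalysis(
        survey=survey,
        consensus=consensus,
        clustering=clustering,
        contingency=table,
        gtest=g_test(table),
    )
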