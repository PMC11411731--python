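"""High-level pipeline: score → decide → filter → classify → chain."""

from __future__ import annotations

from typing import Sequence

from .chaining import PanelTable, chain_linkages
from .decision import (
    ContinuityTable,
    LinkSet,
    apply_city_filter,
    classify_continuity,
    select_linkages,
)
from .model import RunConfig, YearCohort
from .scoring import SimilarityMatrix, build_similarity_matrix

__all__ = ["link_cohorts", "link_panel"]


def link_cohorts(
    cohort1: YearCohort, cohort2: YearCohort, config: RunConfig | None = None
) -> tuple[SimilarityMatrix, LinkSet, ContinuityTable]:
    """Full linkage decision between two adjacent annual cohorts."""
    config = config or RunConfig()
    sm = build_similarity_matrix(cohort1, cohort2, config)
    links = select_linkages(sm, config)
    links = apply_city_filter(links, cohort1, cohort2, config)
    continuity = classify_continuity(links, sm)
    return sm, links, continuity


def link_panel(
    cohorts: Sequence[YearCohort], config: RunConfig | None = None
) -> tuple[list[LinkSet], PanelTable]:
    """Pairwise linkage over consecutive cohorts, chained into a panel."""
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts to link")
    linksets = [
        link_cohorts(c1, c2, config)[1] for c1, c2 in zip(cohorts, cohorts[1:])
    ]
    return linksets, chain_linkages(linksets)
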