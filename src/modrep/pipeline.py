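"""In-memory end-to-end pipeline: enrichment -> prognosis -> sensitivity -> linkage."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .enrichment import DEFAULT_MIN_SET_SIZE, EnrichmentMatrix, RankDirection, enrich
from .io import DrugActivityRecord, ExpressionCohort, GeneSetCollection
from .linkage import DrugDiseaseLink, DrugRanking, link_drugs, rank_drugs
from .prognosis import DEFAULT_ALPHA, ModuleSelection, select_modules
from .sensitivity import (
    DEFAULT_COVERAGE_FRAC,
    DEFAULT_MIN_PAIRS,
    ActivityMatrix,
    SensitivityModule,
    aggregate_activity,
    build_sensitivity_modules,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    enrichment: dict[str, EnrichmentMatrix]
    selection: ModuleSelection
    activity: ActivityMatrix
    sens_modules: list[SensitivityModule]
    links: list[DrugDiseaseLink]
    ranking: DrugRanking
    universe: set[str]


def run_pipeline(
    cohorts: list[ExpressionCohort],
    collection: GeneSetCollection,
    cell_expr: ExpressionCohort,
    records: list[DrugActivityRecord],
    alpha_prognosis: float = DEFAULT_ALPHA,
    alpha_sensitivity: float = DEFAULT_ALPHA,
    alpha_link: float = DEFAULT_ALPHA,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    coverage_frac: float = DEFAULT_COVERAGE_FRAC,
    direction: RankDirection = "descending",
    bh: bool = False,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all intermediates.

    The linkage universe is the set of genes measured in *both* the disease
    cohorts and the cell-line baseline profile.
    """
    enrichment = {
        c.cohort_id: enrich(c.values, collection, min_set_size=min_set_size,
                            direction=direction)
        for c in cohorts
    }
    selection = select_modules(
        {c.cohort_id: (enrichment[c.cohort_id], c.outcome) for c in cohorts},
        alpha=alpha_prognosis,
        bh=bh,
    )
    if not selection.selected:
        logger.warning("no prognostic modules selected; linkage will be empty")

    activity = aggregate_activity(records, coverage_frac=coverage_frac)
    sens_modules = build_sensitivity_modules(
        cell_expr, activity, alpha=alpha_sensitivity, min_pairs=min_pairs
    )

    universe = set(cell_expr.genes)
    for c in cohorts:
        universe &= set(c.genes)

    prog_sets = {name: collection[name].members for name in selection.selected}
    if prog_sets:
        links = link_drugs(prog_sets, sens_modules, universe, alpha=alpha_link)
        ranking = rank_drugs(links, len(prog_sets), alpha=alpha_link)
    else:
        links = []
        ranking = None
    return PipelineResult(
        enrichment=enrichment,
        selection=selection,
        activity=activity,
        sens_modules=sens_modules,
        links=links,
        ranking=ranking,
        universe=universe,
    )
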