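"""End-to-end reconstruction: expression + epigenomes in, core GRN out.

Chains the stages in the order the method prescribes: activity calls,
correlation filtering, identity-TF selection, rank z-scores, active-region
calling, DNase-filtered binding events, scaffold assembly, co-factor
selection, core restriction and Boolean-rule compilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .intervals import PeakSet
from .logic import (
    CooperativityModel,
    LogicRule,
    RegionClause,
    build_logic_rule,
    cluster_region_tfs,
)
from .network import (
    CoreGRN,
    GRNScaffold,
    assemble_core_grn,
    build_scaffold,
    select_cofactors,
)
from .regions import (
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    BindingEvent,
    PromoterAnnotation,
    RegulatoryRegion,
    call_active_enhancers,
    call_active_promoters,
    call_binding_events,
)
from .specificity import (
    DEFAULT_ACTIVITY_ALPHA,
    DEFAULT_COFACTOR_Z,
    DEFAULT_CORRELATION_CUTOFF,
    ActivityCall,
    CofactorZscore,
    ExpressionCompendium,
    SpecificityResult,
    activation_probability,
    call_activity,
    compendium_rank_zscores,
    filter_correlated_samples,
    select_identity_tfs,
)

__all__ = [
    "ReconstructionParams",
    "ReconstructionResult",
    "active_regions_by_gene",
    "activation_marginals",
    "reconstruct_core_grn",
]


@dataclass
class ReconstructionParams:
    """All tunables of a reconstruction run, shipped with their defaults."""

    n_identity: int = 10
    correlation_cutoff: float = DEFAULT_CORRELATION_CUTOFF
    activity_alpha: float = DEFAULT_ACTIVITY_ALPHA
    cofactor_z: float = DEFAULT_COFACTOR_Z
    overlap_threshold: float | None = None  # None -> cooperativity default
    promoter_upstream: int = PROMOTER_UPSTREAM
    promoter_downstream: int = PROMOTER_DOWNSTREAM


@dataclass
class ReconstructionResult:
    core: CoreGRN
    scaffold: GRNScaffold
    identity: list[SpecificityResult]
    activity: dict[str, ActivityCall]
    zscores: dict[str, CofactorZscore]
    events: list[BindingEvent]
    regions: dict[str, RegulatoryRegion] = field(default_factory=dict)


def active_regions_by_gene(
    promoters: list[PromoterAnnotation],
    enhancer_map: pd.DataFrame,
    h3k4me3: PeakSet,
    h3k27ac: PeakSet,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> dict[str, list[RegulatoryRegion]]:
    """Active promoter and enhancer regions of one cell type, per gene."""
    regions = call_active_promoters(promoters, h3k4me3, upstream, downstream)
    regions += call_active_enhancers(enhancer_map, h3k27ac)
    by_gene: dict[str, list[RegulatoryRegion]] = {}
    for r in regions:
        by_gene.setdefault(r.gene, []).append(r)
    return by_gene


def activation_marginals(
    profile: pd.Series, compendium: ExpressionCompendium, genes: list[str]
) -> dict[str, float]:
    """Per-gene empirical P(active) of a cell type's expression profile."""
    out = {}
    for g in genes:
        if g not in profile.index or g not in compendium.values.index:
            raise KeyError(f"{g} missing from profile or compendium")
        out[g] = activation_probability(
            float(profile[g]), compendium.values.loc[g].values
        )
    return out


def _rules_for_core(
    core: CoreGRN,
    events: list[BindingEvent],
    coop: CooperativityModel,
) -> dict[str, LogicRule]:
    """Compile one rule per core node from its active regions' events.

    Only events of core TFs count. The promoter clause is always built (a
    promoterless node was dropped upstream), possibly with no bound TFs;
    enhancer clauses exist only for enhancer regions with >= 1 binding event.
    """
    node_set = set(core.tfs)
    by_region: dict[str, list[BindingEvent]] = {}
    for ev in events:
        if ev.tf in node_set:
            by_region.setdefault(ev.region_id, []).append(ev)
    rules: dict[str, LogicRule] = {}
    for t in core.tfs:
        prom_clause: RegionClause | None = None
        enh_clauses: list[RegionClause] = []
        for region in core.regions.get(t, []):
            if not region.active:
                continue
            evs = by_region.get(region.region_id, [])
            if region.kind == "promoter":
                prom_clause = (
                    cluster_region_tfs(evs, coop)
                    if evs
                    else RegionClause(region_id=region.region_id, clusters=[])
                )
            elif evs:
                enh_clauses.append(cluster_region_tfs(evs, coop))
        rules[t] = build_logic_rule(t, prom_clause, enh_clauses)
    return rules


def reconstruct_core_grn(
    query: pd.Series,
    compendium: ExpressionCompendium,
    promoters: list[PromoterAnnotation],
    enhancer_map: pd.DataFrame,
    h3k4me3: PeakSet,
    h3k27ac: PeakSet,
    dnase: PeakSet,
    tf_peaks: dict[str, PeakSet],
    ppi: set[frozenset],
    params: ReconstructionParams | None = None,
) -> ReconstructionResult:
    """Reconstruct the query cell type's core GRN with Boolean rules."""
    params = params or ReconstructionParams()
    activity = call_activity(query, compendium, alpha=params.activity_alpha)
    filtered = filter_correlated_samples(
        query, compendium, cutoff=params.correlation_cutoff
    )
    identity = select_identity_tfs(query, filtered, n=params.n_identity)
    identity_tfs = [r.tf for r in identity]
    zscores = compendium_rank_zscores(query, filtered)

    by_gene = active_regions_by_gene(
        promoters,
        enhancer_map,
        h3k4me3,
        h3k27ac,
        params.promoter_upstream,
        params.promoter_downstream,
    )
    all_regions = [r for regs in by_gene.values() for r in regs]
    active = [r for r in all_regions if r.active]
    events = call_binding_events(active, tf_peaks, dnase)
    region_index = {r.region_id: r for r in all_regions}

    scaffold = build_scaffold(events, activity, region_index)
    cofactors = select_cofactors(
        scaffold, identity_tfs, activity, zscores, z_cutoff=params.cofactor_z
    )
    core = assemble_core_grn(scaffold, identity_tfs, cofactors, by_gene)
    coop = (
        CooperativityModel(ppi=ppi)
        if params.overlap_threshold is None
        else CooperativityModel(ppi=ppi, overlap_threshold=params.overlap_threshold)
    )
    core.rules = _rules_for_core(core, events, coop)
    return ReconstructionResult(
        core=core,
        scaffold=scaffold,
        identity=identity,
        activity=activity,
        zscores=zscores,
        events=events,
        regions=region_index,
    )
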