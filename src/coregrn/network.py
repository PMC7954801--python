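"""GRN scaffold assembly, co-factor selection and gold-standard comparison.

The scaffold holds every regulatory interaction supported by a binding event
of an active TF inside an active regulatory region of an active target. The
core network restricts the scaffold to the identity TFs plus their
co-factors: active TFs, rank-enriched in the query (specificity-rank z-score
<= -1.5), that both regulate and are regulated by at least one identity TF.
There is no cap on the number of co-factors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .intervals import GenomicInterval
from .logic import LogicRule, RegionClause, rule_from_text, rule_to_text
from .regions import BindingEvent, RegulatoryRegion
from .specificity import DEFAULT_COFACTOR_Z, ActivityCall, CofactorZscore

__all__ = [
    "GRNScaffold",
    "CoreGRN",
    "GoldStandardComparison",
    "build_scaffold",
    "select_cofactors",
    "assemble_core_grn",
    "compare_to_gold_standard",
    "edges_to_frame",
]


@dataclass
class GRNScaffold:
    """Directed TF -> target graph with per-edge supporting evidence.

    Edge attributes: ``kinds`` (region kinds supporting the edge) and
    ``events`` (binding-event ids).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


@dataclass
class CoreGRN:
    """Identity TFs + co-factors with all interactions among them."""

    identity_tfs: list[str]
    cofactors: list[str]
    graph: nx.DiGraph
    regions: dict[str, list[RegulatoryRegion]] = field(default_factory=dict)
    rules: dict[str, LogicRule] = field(default_factory=dict)

    @property
    def tfs(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "identity_tfs": self.identity_tfs,
            "cofactors": self.cofactors,
            "edges": [
                {
                    "regulator": u,
                    "target": v,
                    "kinds": sorted(d.get("kinds", [])),
                    "events": sorted(d.get("events", [])),
                }
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
            "regions": {
                gene: [
                    {
                        "region_id": r.region_id,
                        "element_id": r.element_id,
                        "kind": r.kind,
                        "chrom": r.interval.chrom,
                        "start": r.interval.start,
                        "end": r.interval.end,
                        "active": r.active,
                    }
                    for r in regs
                ]
                for gene, regs in sorted(self.regions.items())
            },
            "rules": [rule_to_text(self.rules[t]) for t in sorted(self.rules)],
        }
        Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CoreGRN":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        g = nx.DiGraph()
        g.add_nodes_from(doc["identity_tfs"])
        g.add_nodes_from(doc["cofactors"])
        for e in doc["edges"]:
            g.add_edge(
                e["regulator"],
                e["target"],
                kinds=set(e["kinds"]),
                events=list(e["events"]),
            )
        regions = {
            gene: [
                RegulatoryRegion(
                    region_id=r["region_id"],
                    gene=gene,
                    kind=r["kind"],
                    interval=GenomicInterval(r["chrom"], r["start"], r["end"]),
                    active=r["active"],
                    element_id=r["element_id"],
                )
                for r in regs
            ]
            for gene, regs in doc["regions"].items()
        }
        rules = {}
        for line in doc["rules"]:
            rule = rule_from_text(line)
            rules[rule.target] = rule
        return cls(
            identity_tfs=list(doc["identity_tfs"]),
            cofactors=list(doc["cofactors"]),
            graph=g,
            regions=regions,
            rules=rules,
        )


@dataclass(frozen=True)
class GoldStandardComparison:
    gs_interactions: int
    inferred_interactions: int
    matching: int
    mismatching: int
    newly_inferred: int
    overall_validated: float


def build_scaffold(
    events: list[BindingEvent],
    activity: dict[str, ActivityCall],
    regions: dict[str, RegulatoryRegion],
) -> GRNScaffold:
    """Edge (A -> B) iff an active TF A has a binding event in an active
    region of an active gene B; edges carry the supporting region kinds."""
    g = nx.DiGraph()

    def is_active(gene: str) -> bool:
        call = activity.get(gene)
        return call is not None and call.active

    for gene, call in activity.items():
        if call.active:
            g.add_node(gene)
    for ev in events:
        region = regions.get(ev.region_id)
        if region is None:
            raise KeyError(f"binding event references unknown region {ev.region_id}")
        if not (is_active(ev.tf) and is_active(ev.target_gene)):
            continue
        if g.has_edge(ev.tf, ev.target_gene):
            d = g.edges[ev.tf, ev.target_gene]
            d["kinds"].add(region.kind)
            d["events"].append(ev.event_id)
        else:
            g.add_edge(
                ev.tf, ev.target_gene, kinds={region.kind}, events=[ev.event_id]
            )
    return GRNScaffold(graph=g)


def select_cofactors(
    scaffold: GRNScaffold,
    identity: list[str],
    activity: dict[str, ActivityCall],
    zscores: dict[str, CofactorZscore],
    z_cutoff: float = DEFAULT_COFACTOR_Z,
) -> set[str]:
    """All TFs meeting the four co-factor conditions (no cap on count).

    Conditions: active; rank z-score <= cutoff; >= 1 outgoing edge to an
    identity TF; >= 1 incoming edge from an identity TF. Promoter- and
    enhancer-mediated edges both count. Identity TFs themselves are excluded.
    """
    present = [t for t in identity if t in scaffold.nodes]
    missing = sorted(set(identity) - set(present))
    if missing:
        warnings.warn(f"identity TFs absent from scaffold: {missing}")
    id_set = set(present)
    cofactors = set()
    for tf in scaffold.nodes - id_set:
        call = activity.get(tf)
        if call is None or not call.active:
            continue
        zs = zscores.get(tf)
        if zs is None or not (zs.z <= z_cutoff):
            continue
        regulates = any(t in id_set for t in scaffold.graph.successors(tf))
        regulated = any(s in id_set for s in scaffold.graph.predecessors(tf))
        if regulates and regulated:
            cofactors.add(tf)
    return cofactors


def assemble_core_grn(
    scaffold: GRNScaffold,
    identity: list[str],
    cofactors: set[str],
    regions: dict[str, list[RegulatoryRegion]] | None = None,
) -> CoreGRN:
    """Node-induced subgraph of the scaffold over identity + co-factors.

    ``regions`` maps gene -> its active regulatory regions; nodes without an
    active promoter are dropped with a warning (they cannot be induced under
    the promoter-AND-enhancer rule semantics).
    """
    regions = regions or {}
    nodes = [t for t in identity if t in scaffold.nodes] + sorted(cofactors)
    if regions:
        kept = []
        for t in nodes:
            has_prom = any(
                r.kind == "promoter" and r.active for r in regions.get(t, [])
            )
            if has_prom:
                kept.append(t)
            else:
                warnings.warn(f"{t} has no active promoter; dropped from core GRN")
        nodes = kept
    if not nodes:
        raise ValueError("core GRN would be empty")
    sub = scaffold.graph.subgraph(nodes).copy()
    return CoreGRN(
        identity_tfs=[t for t in identity if t in nodes],
        cofactors=[t for t in sorted(cofactors) if t in nodes],
        graph=sub,
        regions={t: regions.get(t, []) for t in nodes},
    )


def compare_to_gold_standard(
    inferred: set[tuple[str, str]] | list[tuple[str, str]],
    gold_standard: set[tuple[str, str]] | list[tuple[str, str]],
) -> GoldStandardComparison:
    """Edge-set agreement restricted to TFs present on both sides.

    Only TFs appearing in both the inferred and gold-standard node sets are
    considered; edges touching other TFs are excluded before counting.
    """
    inferred = set(map(tuple, inferred))
    gs = set(map(tuple, gold_standard))
    inf_tfs = {t for e in inferred for t in e}
    gs_tfs = {t for e in gs for t in e}
    shared = inf_tfs & gs_tfs
    if not shared:
        raise ValueError("no TFs shared between inferred and gold-standard networks")
    inferred = {e for e in inferred if e[0] in shared and e[1] in shared}
    gs = {e for e in gs if e[0] in shared and e[1] in shared}
    matching = len(gs & inferred)
    return GoldStandardComparison(
        gs_interactions=len(gs),
        inferred_interactions=len(inferred),
        matching=matching,
        mismatching=len(gs - inferred),
        newly_inferred=len(inferred - gs),
        overall_validated=100.0 * matching / len(gs) if gs else 0.0,
    )


def edges_to_frame(grn: CoreGRN) -> pd.DataFrame:
    """Edge-list export: regulator, target, region_kinds, n_events."""
    rows = [
        {
            "regulator": u,
            "target": v,
            "region_kinds": ",".join(sorted(d.get("kinds", []))),
            "n_events": len(d.get("events", [])),
        }
        for u, v, d in sorted(grn.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["regulator", "target", "region_kinds", "n_events"])
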