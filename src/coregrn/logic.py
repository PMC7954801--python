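"""Cooperativity inference and per-target Boolean rule compilation.

TFs bound in one regulatory region either cooperate (bind as a complex) or
compete for the site. Two TFs are called cooperative when their binding peaks
in the region show a reciprocal overlap of at least a calibrated threshold
(62.43% by default) AND a protein-protein interaction between them is on
record. The undirected graph of cooperative pairs is split into connected
components; each component is one AND-cluster, and clusters within a region
combine by OR.

The rule of a target gene is

    promoter_clause AND (enhancer_1 OR enhancer_2 OR ...)

with every literal positive (no repression in this model). A target with no
active enhancer is governed by its promoter clause alone; a clause with no
bound TFs is vacuously true; a target with no regulators at all maintains
its current state.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .intervals import reciprocal_overlap
from .regions import BindingEvent

__all__ = [
    "DEFAULT_OVERLAP_THRESHOLD",
    "CooperativityModel",
    "RegionClause",
    "LogicRule",
    "read_ppi",
    "calibrate_overlap_threshold",
    "cluster_region_tfs",
    "build_logic_rule",
    "evaluate_rule",
    "rule_to_text",
    "rule_from_text",
]

#: Reciprocal peak overlap above which a PPI-supported pair is cooperative.
DEFAULT_OVERLAP_THRESHOLD = 0.6243


@dataclass
class CooperativityModel:
    """PPI evidence plus the reciprocal-overlap threshold."""

    ppi: set[frozenset] = field(default_factory=set)
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must be in [0, 1]")

    def has_ppi(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.ppi


@dataclass
class RegionClause:
    """OR of AND-clusters over the TFs bound in one region."""

    region_id: str
    clusters: list[frozenset] = field(default_factory=list)

    @property
    def tfs(self) -> frozenset:
        return frozenset(itertools.chain.from_iterable(self.clusters))

    def evaluate(self, state: dict[str, bool]) -> bool:
        """True if any cluster has all members active; vacuously true when
        the region binds no TFs."""
        if not self.clusters:
            return True
        missing = self.tfs - state.keys()
        if missing:
            raise KeyError(f"state does not assign {sorted(missing)}")
        return any(all(state[t] for t in cl) for cl in self.clusters)


@dataclass
class LogicRule:
    """Boolean update rule of one target TF (all literals positive)."""

    target: str
    promoter_clause: RegionClause | None = None
    enhancer_clauses: list[RegionClause] = field(default_factory=list)

    @property
    def regulators(self) -> frozenset:
        tfs = set()
        if self.promoter_clause is not None:
            tfs |= self.promoter_clause.tfs
        for cl in self.enhancer_clauses:
            tfs |= cl.tfs
        return frozenset(tfs)

    @property
    def self_maintaining(self) -> bool:
        return not self.regulators


def read_ppi(path) -> set[frozenset]:
    """2-column TSV of unordered interacting gene-symbol pairs."""
    pairs = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0] or fields[0].startswith("#"):
                continue
            pairs.add(frozenset(fields[:2]))
    return pairs


def calibrate_overlap_threshold(
    positive_pairs: np.ndarray, negative_pairs: np.ndarray, step: float = 1e-4
) -> float:
    """Overlap threshold maximizing balanced accuracy on labeled pairs.

    ``positive_pairs``/``negative_pairs`` hold reciprocal-overlap values of
    interacting and non-interacting TF pairs. Pairs at or above a candidate
    threshold are classified interacting; the sweep runs over [0, 1] in
    ``step`` increments with ties resolved toward the larger threshold.
    Warns when the classes are inseparable (best balanced accuracy ~ 0.5).
    """
    pos = np.asarray(positive_pairs, dtype=float)
    neg = np.asarray(negative_pairs, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both pair classes must be non-empty")
    grid = np.arange(0.0, 1.0 + step / 2, step)
    # vectorized sweep: TPR and TNR at every candidate threshold
    tpr = (pos[None, :] >= grid[:, None]).mean(axis=1)
    tnr = (neg[None, :] < grid[:, None]).mean(axis=1)
    bacc = (tpr + tnr) / 2
    best = bacc.max()
    idx = int(np.flatnonzero(bacc >= best - 1e-12)[-1])  # ties -> larger threshold
    if best < 0.55:
        warnings.warn(
            f"overlap calibration barely separates classes "
            f"(balanced accuracy {best:.3f})"
        )
    return float(grid[idx])


def cluster_region_tfs(
    events: list[BindingEvent], model: CooperativityModel
) -> RegionClause:
    """Partition the TFs of one region into cooperative AND-clusters.

    Edge between two TFs iff their maximal pairwise reciprocal peak overlap
    is >= the threshold AND a PPI is on record; clusters are the connected
    components. Deterministic: clusters sorted by their lexicographically
    smallest member.
    """
    if not events:
        raise ValueError("no binding events supplied")
    region_ids = {e.region_id for e in events}
    if len(region_ids) != 1:
        raise ValueError(f"events span multiple regions: {sorted(region_ids)}")
    peaks_by_tf: dict[str, list] = {}
    for e in events:
        peaks_by_tf.setdefault(e.tf, []).append(e.peak)
    g = nx.Graph()
    g.add_nodes_from(peaks_by_tf)
    for a, b in itertools.combinations(sorted(peaks_by_tf), 2):
        if not model.has_ppi(a, b):
            continue
        best = max(
            reciprocal_overlap(pa, pb)
            for pa in peaks_by_tf[a]
            for pb in peaks_by_tf[b]
        )
        if best >= model.overlap_threshold:
            g.add_edge(a, b)
    clusters = sorted(
        (frozenset(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )
    return RegionClause(region_id=region_ids.pop(), clusters=clusters)


def build_logic_rule(
    target: str,
    promoter_clause: RegionClause | None,
    enhancer_clauses: list[RegionClause],
) -> LogicRule:
    """Assemble a target's rule: promoter AND (OR over enhancer clauses).

    The target must have an active promoter (possibly with no bound TFs);
    nodes without one are dropped before rule building because they cannot
    be induced under these semantics.
    """
    if promoter_clause is None:
        raise ValueError(
            f"{target} lacks an active promoter; cannot build a logic rule"
        )
    return LogicRule(
        target=target,
        promoter_clause=promoter_clause,
        enhancer_clauses=list(enhancer_clauses),
    )


def evaluate_rule(rule: LogicRule, state: dict[str, bool]) -> bool:
    """Evaluate a rule on a full TF state assignment.

    Self-maintaining rules return the target's current value (which must be
    assigned). Enhancer clauses combine by OR; a rule without enhancer
    clauses is the promoter clause alone.
    """
    if rule.self_maintaining:
        if rule.target not in state:
            raise KeyError(f"state does not assign {rule.target}")
        return bool(state[rule.target])
    prom_ok = (
        rule.promoter_clause.evaluate(state)
        if rule.promoter_clause is not None
        else True
    )
    if not rule.enhancer_clauses:
        return prom_ok
    return prom_ok and any(cl.evaluate(state) for cl in rule.enhancer_clauses)


# ---------------------------------------------------------------------------
# plain-text serialization:  target <- (A & B | C) & ((D) | (E & F))
# promoter clause first, enhancer group double-parenthesized; "." marks a
# self-maintaining rule. Clause region ids ride in an optional [id] suffix.


def _clause_to_text(clause: RegionClause) -> str:
    if not clause.clusters:
        body = "1"
    else:
        body = " | ".join(
            " & ".join(sorted(cl)) for cl in clause.clusters
        )
    return f"({body})[{clause.region_id}]"


def rule_to_text(rule: LogicRule) -> str:
    if rule.self_maintaining and rule.promoter_clause is None:
        return f"{rule.target} <- ."
    parts = []
    if rule.promoter_clause is not None:
        parts.append(_clause_to_text(rule.promoter_clause))
    if rule.enhancer_clauses:
        inner = " | ".join(_clause_to_text(c) for c in rule.enhancer_clauses)
        parts.append(f"({inner})")
    return f"{rule.target} <- " + " & ".join(parts)


_CLAUSE_RE = re.compile(r"\(([^()]*)\)\[([^\]]*)\]")


def _clause_from_text(text: str) -> RegionClause:
    m = _CLAUSE_RE.fullmatch(text.strip())
    if not m:
        raise ValueError(f"malformed clause: {text!r}")
    body, region_id = m.group(1).strip(), m.group(2)
    clusters = []
    if body != "1":
        for part in body.split("|"):
            members = frozenset(t.strip() for t in part.split("&"))
            clusters.append(members)
        clusters.sort(key=min)
    return RegionClause(region_id=region_id, clusters=clusters)


def rule_from_text(line: str) -> LogicRule:
    """Parse a serialized rule line (round-trips with :func:`rule_to_text`)."""
    target, _, rhs = line.partition("<-")
    target, rhs = target.strip(), rhs.strip()
    if not target or not rhs:
        raise ValueError(f"malformed rule line: {line!r}")
    if rhs == ".":
        return LogicRule(target=target)
    prom_text, _, enh_group = rhs.partition(" & (")
    prom = _clause_from_text(prom_text)
    enh: list[RegionClause] = []
    if enh_group:
        inner = enh_group.rstrip()
        if not inner.endswith(")"):
            raise ValueError(f"malformed enhancer group in: {line!r}")
        enh = [_clause_from_text(m.group(0)) for m in _CLAUSE_RE.finditer(inner[:-1])]
    return LogicRule(target=target, promoter_clause=prom, enhancer_clauses=enh)
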