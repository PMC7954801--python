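"""Markov-chain surrogate of conversion efficiency.

The core GRN with its Boolean rules defines a deterministic synchronous
transition system over TF states; stochasticity enters only through the
prior over initial states, a product of per-TF empirical activation
probabilities taken from the initial cell type's expression profile.
Over-expressed TFs are clamped active for the whole simulation (sustained
cassette expression), which also forces their prior marginal to 1.

Transcriptional score T: the prior mass of initial states from which the
clamped dynamics eventually reach the all-active state (default,
``reachability``), or the same mass weighted by how quickly they get there
(``distance_weighted``). Epigenetic score E: the product over network TFs of
the fraction of target-active regulatory regions already active in the
initial cell type; the fraction is 1 for over-expressed TFs (remodeling is
bypassed) and for TFs with no target-active regions. The surrogate
efficiency of a TF combination is the arithmetic mean (T + E) / 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .logic import LogicRule
from .network import CoreGRN
from .regions import RegulatoryRegion
from .intervals import overlap_length

__all__ = [
    "EXACT_MODE_MAX_TFS",
    "BooleanNetworkModel",
    "PriorModel",
    "ScoreBreakdown",
    "RankingResult",
    "compile_model",
    "state_prior",
    "synchronous_successor",
    "distance_to_full_activation",
    "reachability_distances",
    "transcriptional_score",
    "epigenetic_score",
    "combined_score",
    "score_perturbation",
    "rank_combinations",
    "ranking_concordance_pvalue",
]

#: Largest network for which exact state enumeration is permitted (~4M states).
EXACT_MODE_MAX_TFS = 22
INF = float("inf")


@dataclass
class BooleanNetworkModel:
    """Compiled synchronous Boolean network over an ordered TF list.

    States are integers: bit ``i`` is the activity of ``tfs[i]``. Each
    node's rule is compiled to bitmask clusters; ``clamp`` holds the indices
    of over-expressed TFs, forced to 1 at every step.
    """

    tfs: list[str]
    rules: dict[str, LogicRule]
    clamp: frozenset = frozenset()
    # compiled per node: None = self-maintenance, else
    # (promoter cluster masks, list of enhancer clause cluster-mask lists)
    _compiled: list = field(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return len(self.tfs)

    @property
    def all_active(self) -> int:
        return (1 << self.n) - 1

    @property
    def clamp_mask(self) -> int:
        m = 0
        for i in self.clamp:
            m |= 1 << i
        return m

    def with_clamp(self, tf_names: set[str] | list[str]) -> "BooleanNetworkModel":
        idx = {t: i for i, t in enumerate(self.tfs)}
        missing = set(tf_names) - idx.keys()
        if missing:
            raise KeyError(f"clamped TFs not in network: {sorted(missing)}")
        return replace(
            self, clamp=frozenset(idx[t] for t in tf_names), _compiled=self._compiled
        )


def _cluster_masks(clusters, idx: dict[str, int]) -> list[int]:
    masks = []
    for cl in clusters:
        m = 0
        for tf in cl:
            m |= 1 << idx[tf]
        masks.append(m)
    return masks


def compile_model(
    tfs: list[str], rules: dict[str, LogicRule], clamp: set[str] | None = None
) -> BooleanNetworkModel:
    """Compile logic rules into a bitmask transition model.

    Every TF must have a rule or is treated as self-maintaining; regulators
    must all be network TFs.
    """
    if len(tfs) > 60:
        raise ValueError("networks beyond 60 TFs are not supported")
    idx = {t: i for i, t in enumerate(tfs)}
    compiled = []
    for t in tfs:
        rule = rules.get(t)
        if rule is None or rule.self_maintaining:
            compiled.append(None)
            continue
        unknown = rule.regulators - idx.keys()
        if unknown:
            raise KeyError(f"rule for {t} uses non-network TFs {sorted(unknown)}")
        prom = (
            _cluster_masks(rule.promoter_clause.clusters, idx)
            if rule.promoter_clause is not None
            else []
        )
        enh = [_cluster_masks(cl.clusters, idx) for cl in rule.enhancer_clauses]
        compiled.append((prom, enh))
    model = BooleanNetworkModel(tfs=list(tfs), rules=dict(rules), _compiled=compiled)
    if clamp:
        model = model.with_clamp(clamp)
    return model


@dataclass
class PriorModel:
    """Independent per-TF activation probabilities plus a perturbation set."""

    marginals: dict[str, float]
    perturbation: frozenset = frozenset()

    def __post_init__(self) -> None:
        for tf, p in self.marginals.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"marginal of {tf} outside [0, 1]: {p}")

    def effective_marginals(self, tfs: list[str]) -> np.ndarray:
        """Marginals in network node order with clamped TFs forced to 1."""
        out = np.array([self.marginals.get(t, 0.0) for t in tfs], dtype=float)
        for i, t in enumerate(tfs):
            if t in self.perturbation:
                out[i] = 1.0
        return out


@dataclass(frozen=True)
class ScoreBreakdown:
    transcriptional: float
    epigenetic: float
    combined: float
    per_tf_fractions: dict = field(default_factory=dict)
    mode: str = "exact"
    variant: str = "reachability"
    n_samples: int | None = None
    seed: int | None = None


@dataclass
class RankingResult:
    k: int
    combinations: list[tuple[tuple[str, ...], ScoreBreakdown]]


def state_prior(state: int, prior: PriorModel, tfs: list[str]) -> float:
    """Product-form probability of one network state under the prior."""
    marg = prior.effective_marginals(tfs)
    p = 1.0
    for i in range(len(tfs)):
        p *= marg[i] if (state >> i) & 1 else 1.0 - marg[i]
    return p


def synchronous_successor(state: int, model: BooleanNetworkModel) -> int:
    """One synchronous step: every free TF takes its rule's value; clamped
    TFs stay 1; self-maintaining TFs keep their value."""
    nxt = 0
    for i in range(model.n):
        comp = model._compiled[i]
        if comp is None:
            bit = (state >> i) & 1
        else:
            prom, enh = comp
            ok = (not prom) or any((state & m) == m for m in prom)
            if ok and enh:
                ok = any(
                    (not clause) or any((state & m) == m for m in clause)
                    for clause in enh
                )
            bit = 1 if ok else 0
        nxt |= bit << i
    return (nxt | model.clamp_mask)


def distance_to_full_activation(
    state: int, model: BooleanNetworkModel, max_steps: int | None = None
) -> float:
    """Synchronous steps until the all-active state; inf on a cycle.

    The trajectory is deterministic, so revisiting a state before reaching
    all-active proves unreachability.
    """
    target = model.all_active
    limit = max_steps if max_steps is not None else (1 << model.n) + 1
    seen = set()
    s = state
    for step in range(limit + 1):
        if s == target:
            return float(step)
        if s in seen:
            return INF
        seen.add(s)
        s = synchronous_successor(s, model)
    return INF


def reachability_distances(model: BooleanNetworkModel) -> dict[int, float]:
    """Distance to full activation for every state, with path memoization."""
    dist: dict[int, float] = {model.all_active: 0.0}
    for s0 in range(1 << model.n):
        if s0 in dist:
            continue
        path = []
        on_path = {}
        s = s0
        while s not in dist and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = synchronous_successor(s, model)
        if s in dist:
            base = dist[s]
            for i, st in enumerate(reversed(path)):
                dist[st] = base + i + 1 if math.isfinite(base) else INF
        else:  # closed a new cycle: everything on the path diverges
            for st in path:
                dist[st] = INF
    return dist


def transcriptional_score(
    model: BooleanNetworkModel,
    prior: PriorModel,
    mode: str = "exact",
    variant: str = "reachability",
    n_samples: int = 10_000,
    seed: int | None = None,
) -> float:
    """Prior-weighted score of eventually reaching the all-active state.

    ``reachability``: T = sum_s pi(s) * 1[d(s) < inf]. ``distance_weighted``:
    the indicator is scaled by 1 - d(s)/(d_max + 1) with d_max the largest
    finite distance observed (pure reachability mass when d_max = 0). Exact
    mode enumerates all 2^n states (n <= 22); Monte-Carlo draws initial
    states from the prior and needs a seed.
    """
    if variant not in ("reachability", "distance_weighted"):
        raise ValueError(f"unknown variant {variant!r}")
    marg = prior.effective_marginals(model.tfs)
    clamp_names = {model.tfs[i] for i in model.clamp}
    if clamp_names - prior.perturbation:
        marg = marg.copy()
        for i in model.clamp:
            marg[i] = 1.0
    if mode == "exact":
        if model.n > EXACT_MODE_MAX_TFS:
            raise ValueError(
                f"exact mode supports n <= {EXACT_MODE_MAX_TFS}; use mode='monte_carlo'"
            )
        dist = reachability_distances(model)
        ds, pis = [], []
        for s in range(1 << model.n):
            p = 1.0
            for i in range(model.n):
                p *= marg[i] if (s >> i) & 1 else 1.0 - marg[i]
            if p > 0.0:
                ds.append(dist[s])
                pis.append(p)
        ds = np.array(ds)
        pis = np.array(pis)
        finite = np.isfinite(ds)
        if variant == "reachability":
            return float(pis[finite].sum())
        d_max = ds[finite].max(initial=0.0)
        w = 1.0 - ds[finite] / (d_max + 1.0)
        return float((pis[finite] * w).sum())
    if mode == "monte_carlo":
        if seed is None:
            raise ValueError("monte_carlo mode requires a seed")
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(seed)
        draws = rng.random((n_samples, model.n)) < marg[None, :]
        weights = np.zeros(n_samples)
        dcache: dict[int, float] = {}
        for j in range(n_samples):
            s = 0
            for i in range(model.n):
                if draws[j, i]:
                    s |= 1 << i
            if s not in dcache:
                dcache[s] = distance_to_full_activation(s, model)
            weights[j] = dcache[s]
        finite = np.isfinite(weights)
        if variant == "reachability":
            return float(finite.mean())
        if not finite.any():
            return 0.0
        d_max = weights[finite].max(initial=0.0)
        w = np.where(finite, 1.0 - np.minimum(weights, d_max) / (d_max + 1.0), 0.0)
        return float(w.mean())
    raise ValueError(f"unknown mode {mode!r}")


def _shared_region_count(
    target_regs: list[RegulatoryRegion], initial_regs: list[RegulatoryRegion]
) -> int:
    """Target regions that are also active initially: same source element and
    >= 1 bp coordinate overlap between the active segments."""
    count = 0
    for tr in target_regs:
        for ir in initial_regs:
            if (
                tr.element_id == ir.element_id
                and overlap_length(tr.interval, ir.interval) >= 1
            ):
                count += 1
                break
    return count


def epigenetic_score(
    initial_regions: dict[str, list[RegulatoryRegion]],
    target_regions: dict[str, list[RegulatoryRegion]],
    perturbation: set[str] | frozenset,
    network_tfs: list[str] | None = None,
    include_promoter: bool = True,
) -> tuple[float, dict[str, float]]:
    """Product over network TFs of the fraction of target-active regions
    already active in the initial cell type.

    Fractions are 1 for perturbed TFs and for TFs whose target cell type has
    no active regions. ``include_promoter=False`` restricts the fraction to
    enhancers. Returns (E, per-TF fractions).
    """
    tfs = network_tfs if network_tfs is not None else sorted(target_regions)
    fractions: dict[str, float] = {}
    for tf in tfs:
        tregs = [
            r
            for r in target_regions.get(tf, [])
            if r.active and (include_promoter or r.kind == "enhancer")
        ]
        if tf in perturbation or not tregs:
            fractions[tf] = 1.0
            continue
        iregs = [r for r in initial_regions.get(tf, []) if r.active]
        fractions[tf] = _shared_region_count(tregs, iregs) / len(tregs)
    e = float(np.prod(list(fractions.values()))) if fractions else 1.0
    return e, fractions


def combined_score(t: float, e: float) -> float:
    """Arithmetic mean of the transcriptional and epigenetic scores."""
    if not (0.0 <= t <= 1.0 and 0.0 <= e <= 1.0):
        raise ValueError(f"scores must lie in [0, 1], got T={t}, E={e}")
    return (t + e) / 2.0


def score_perturbation(
    model: BooleanNetworkModel,
    perturbation: set[str] | tuple[str, ...],
    marginals: dict[str, float],
    initial_regions: dict[str, list[RegulatoryRegion]],
    target_regions: dict[str, list[RegulatoryRegion]],
    mode: str = "exact",
    variant: str = "reachability",
    n_samples: int = 10_000,
    seed: int | None = None,
    include_promoter: bool = True,
) -> ScoreBreakdown:
    """Full surrogate-efficiency breakdown for one TF combination."""
    pset = frozenset(perturbation)
    clamped = model.with_clamp(pset)
    prior = PriorModel(marginals=marginals, perturbation=pset)
    t = transcriptional_score(
        clamped, prior, mode=mode, variant=variant, n_samples=n_samples, seed=seed
    )
    e, fractions = epigenetic_score(
        initial_regions,
        target_regions,
        pset,
        network_tfs=model.tfs,
        include_promoter=include_promoter,
    )
    return ScoreBreakdown(
        transcriptional=t,
        epigenetic=e,
        combined=combined_score(t, e),
        per_tf_fractions=fractions,
        mode=mode,
        variant=variant,
        n_samples=n_samples if mode == "monte_carlo" else None,
        seed=seed if mode == "monte_carlo" else None,
    )


def rank_combinations(
    grn: CoreGRN,
    k: int,
    marginals: dict[str, float],
    initial_regions: dict[str, list[RegulatoryRegion]],
    target_regions: dict[str, list[RegulatoryRegion]] | None = None,
    candidates: list[tuple[str, ...]] | None = None,
    mode: str = "exact",
    variant: str = "reachability",
    n_samples: int = 10_000,
    seed: int | None = None,
    include_promoter: bool = True,
) -> RankingResult:
    """Score and rank every size-k TF combination of the core network.

    Exhaustive when C(n, k) <= 1e6; larger problems need an explicit
    ``candidates`` list. Sorting is by descending combined score with a
    deterministic lexicographic tie-break on the sorted TF names.
    """
    tfs = grn.tfs
    n = len(tfs)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if target_regions is None:
        target_regions = grn.regions
    model = compile_model(tfs, grn.rules)
    if candidates is None:
        if math.comb(n, k) > 1_000_000:
            raise ValueError(
                "combination space too large for exhaustive ranking; "
                "pass an explicit candidate list"
            )
        candidates = [tuple(c) for c in itertools.combinations(tfs, k)]
    scored = []
    for combo in candidates:
        combo = tuple(sorted(combo))
        if len(combo) != k:
            raise ValueError(f"candidate {combo} does not have size {k}")
        br = score_perturbation(
            model,
            combo,
            marginals,
            initial_regions,
            target_regions,
            mode=mode,
            variant=variant,
            n_samples=n_samples,
            seed=seed,
            include_promoter=include_promoter,
        )
        scored.append((combo, br))
    scored.sort(key=lambda cb: (-cb[1].combined, cb[0]))
    return RankingResult(k=k, combinations=scored)


def ranking_concordance_pvalue(
    predicted: list[int],
    experimental: list[int],
    n_draws: int = 100_000,
    seed: int | None = None,
) -> float:
    """Permutation-null tail probability of the rank-vector distance.

    D = Euclidean distance between the two rank vectors; the null compares
    the experimental ranking with all k! permutations, and
    p = #{permutations with distance <= D} / k!. Exhaustive for k <= 8,
    seeded Monte-Carlo beyond.
    """
    pred = list(predicted)
    exp = list(experimental)
    if len(pred) != len(exp):
        raise ValueError("rankings must have equal length")
    k = len(pred)
    if k < 1:
        raise ValueError("rankings must be non-empty")
    for r in (pred, exp):
        if sorted(r) != list(range(1, k + 1)):
            raise ValueError("rankings must be permutations of 1..k")
    exp_arr = np.array(exp, dtype=float)
    d_obs = float(np.linalg.norm(np.array(pred, dtype=float) - exp_arr))
    if k <= 8:
        count = sum(
            1
            for perm in itertools.permutations(range(1, k + 1))
            if np.linalg.norm(np.array(perm, dtype=float) - exp_arr) <= d_obs + 1e-9
        )
        return count / math.factorial(k)
    if seed is None:
        raise ValueError("k > 8 requires a seed for Monte-Carlo sampling")
    rng = np.random.default_rng(seed)
    vals = np.arange(1, k + 1, dtype=float)
    count = 0
    for _ in range(n_draws):
        perm = rng.permutation(vals)
        if np.linalg.norm(perm - exp_arr) <= d_obs + 1e-9:
            count += 1
    return max(count, 1) / n_draws
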