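"""Seeded synthetic data with planted ground truth.

Generates toy genomes, cell-type peak sets, expression compendia, PPI lists
and complete conversion scenarios that exercise every stage of the package
without external downloads. At ``noise_level = 0`` the planted truth is
exactly recoverable: the reconstruction pipeline returns the planted core
network and logic rules, the planted identity TFs are the top-specificity
genes, planted co-factors pass the rank z-score test, and the planted
optimal factor combination scores (T + E) / 2 = 1 and ranks first.

Layout of the toy genome: all genes sit on one chromosome ``chrT`` with
widely spaced TSSs, a promoter window per gene and 1-4 candidate enhancers
downstream of each TSS. Planted regulators bind in fixed slots inside the
active windows; cooperative (AND) pairs get peaks with reciprocal overlap
0.8 plus a PPI record, competitive co-occupants get disjoint peaks, so the
cooperativity threshold (0.6243) separates them with a wide margin.

Expression design: identity TFs are expressed only in the query sample;
co-factors are high in the query, low in the background except for a single
strong "related-sample" bump, which pins their background specificity ranks
near the bottom while keeping the rank variance positive; outsider TFs are
silent in the query and broadly expressed in the background. Per-sample
specificity is a monotone function of the TF's normalized mass on that
sample, which makes these rank guarantees exact at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet, write_intervals
from .logic import LogicRule, RegionClause, rule_to_text
from .regions import (
    PROMOTER_DOWNSTREAM,
    PROMOTER_UPSTREAM,
    PromoterAnnotation,
    define_promoter,
)

__all__ = [
    "FixtureConfig",
    "PlantedRegulation",
    "FixtureBundle",
    "generate_toy_genome",
    "generate_planted_grn",
    "generate_celltype_peaks",
    "generate_expression_compendium",
    "generate_fixture_bundle",
    "generate_conversion_scenario",
    "random_boolean_model",
]

CHROM = "chrT"
GENE_SPACING = 20_000
ENHANCER_LEN = 1_200
SLOT_WIDTH = 200
SLOT_STRIDE = 320
PAIR_SHIFT = 40  # reciprocal overlap of a planted AND pair = 160/200 = 0.8
PROMOTER_SLOTS = 4
ENHANCER_SLOTS = 2


@dataclass
class FixtureConfig:
    """Knobs of the synthetic world; ``seed`` drives all randomness."""

    n_tfs: int = 12
    n_identity: int | None = None
    n_cofactors: int = 2
    n_background_samples: int = 30
    n_phenotypes: int = 5
    genome_length: int | None = None
    mean_enhancers_per_gene: float = 1.5
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.noise_level <= 1.0):
            raise ValueError("noise_level must lie in [0, 1]")
        if self.n_identity is None:
            # keep outsiders comfortably more numerous than identity TFs so
            # that planted co-factor background ranks sit near the bottom
            self.n_identity = min(10, max(2, self.n_tfs // 4))
        if self.n_identity + self.n_cofactors >= self.n_tfs:
            raise ValueError("need at least one non-core TF")
        if self.n_background_samples < max(20, self.n_cofactors + 2):
            raise ValueError(
                "need >= 20 background samples (and one bump sample per co-factor)"
            )


@dataclass
class PlantedRegulation:
    """Ground-truth regulators of one target, grouped into AND-clusters.

    ``promoter_clusters`` and ``enhancer_clusters[j]`` (j = index into the
    target's enhancer list) each hold disjoint TF sets; pairs are planted
    cooperative, singletons competitive.
    """

    target: str
    promoter_clusters: list[frozenset] = field(default_factory=list)
    enhancer_clusters: dict[int, list[frozenset]] = field(default_factory=dict)

    @property
    def regulators(self) -> set[str]:
        regs: set[str] = set()
        for cl in self.promoter_clusters:
            regs |= cl
        for clusters in self.enhancer_clusters.values():
            for cl in clusters:
                regs |= cl
        return regs


@dataclass
class FixtureBundle:
    """Everything one reconstruction-and-scoring run needs, plus the truth."""

    config: FixtureConfig
    promoters: list[PromoterAnnotation]
    enhancer_map: pd.DataFrame
    target_peaks: dict  # assay -> PeakSet; "tf" -> {tf: PeakSet}
    initial_peaks: dict
    compendium: "pd.DataFrame | None"
    phenotypes: pd.Series | None
    query_profile: pd.Series | None
    initial_profile: pd.Series | None
    ppi: set[frozenset]
    identity_tfs: list[str]
    cofactors: list[str]
    outsiders: list[str]
    regulations: dict[str, PlantedRegulation]
    planted_edges: set[tuple[str, str]]
    planted_rules: dict[str, LogicRule]
    optimal_set: tuple[str, ...] | None = None
    essential_tf: str | None = None
    k: int | None = None

    @property
    def core_tfs(self) -> list[str]:
        return self.identity_tfs + self.cofactors

    def write(self, outdir: str | Path) -> Path:
        """Write the bundle as BED/TSV/JSON plus a planted-truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "gene": [p.gene for p in self.promoters],
                "chrom": [p.chrom for p in self.promoters],
                "tss": [p.tss for p in self.promoters],
                "strand": [p.strand for p in self.promoters],
            }
        ).to_csv(outdir / "promoters.tsv", sep="\t", index=False)
        self.enhancer_map.to_csv(outdir / "enhancers.tsv", sep="\t", index=False)
        for celltype, peaks in (("target", self.target_peaks), ("initial", self.initial_peaks)):
            for assay in ("H3K4me3", "H3K27ac", "DNase"):
                write_intervals(peaks[assay], outdir / f"{celltype}_{assay}.bed")
            for tf, ps in sorted(peaks["tf"].items()):
                write_intervals(ps, outdir / f"{celltype}_TF_{tf}.bed")
        if self.compendium is not None:
            self.compendium.to_csv(outdir / "compendium.tsv", sep="\t")
            self.phenotypes.rename("phenotype").to_frame().to_csv(
                outdir / "compendium_metadata.tsv", sep="\t", index_label="sample"
            )
            self.query_profile.to_csv(
                outdir / "query_profile.tsv", sep="\t", header=False
            )
        if self.initial_profile is not None:
            self.initial_profile.to_csv(
                outdir / "initial_profile.tsv", sep="\t", header=False
            )
        with (outdir / "ppi.tsv").open("w", encoding="utf-8") as fh:
            for pair in sorted(tuple(sorted(p)) for p in self.ppi):
                fh.write(f"{pair[0]}\t{pair[1]}\n")
        manifest = {
            "seed": self.config.seed,
            "identity_tfs": self.identity_tfs,
            "cofactors": self.cofactors,
            "outsiders": self.outsiders,
            "edges": sorted(map(list, self.planted_edges)),
            "rules": [rule_to_text(self.planted_rules[t]) for t in sorted(self.planted_rules)],
            "optimal_set": list(self.optimal_set) if self.optimal_set else None,
            "essential_tf": self.essential_tf,
            "k": self.k,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1), encoding="utf-8"
        )
        return outdir


def _gene_names(n: int) -> list[str]:
    return [f"TF{i:02d}" for i in range(1, n + 1)]


def generate_toy_genome(
    config: FixtureConfig,
) -> tuple[list[PromoterAnnotation], pd.DataFrame]:
    """Place ``n_tfs`` genes on one toy chromosome with candidate enhancers.

    Promoter windows never overlap; per-gene enhancer counts are geometric
    with the configured mean (capped at 4), so most genes carry 1-2.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_tfs)
    required = 5_000 + config.n_tfs * GENE_SPACING + 5_000
    if config.genome_length is not None and config.genome_length < required:
        raise ValueError(
            f"genome_length {config.genome_length} too short; need >= {required}"
        )
    promoters = []
    rows = []
    p_geo = min(1.0, 1.0 / max(config.mean_enhancers_per_gene, 1.0))
    for i, gene in enumerate(genes):
        tss = 5_000 + i * GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        promoters.append(
            PromoterAnnotation(gene=gene, chrom=CHROM, tss=tss, strand=strand)
        )
        n_enh = min(4, int(rng.geometric(p_geo)))
        for j in range(n_enh):
            start = tss + 3_000 + j * 2_500
            rows.append(
                {
                    "chrom": CHROM,
                    "start": start,
                    "end": start + ENHANCER_LEN,
                    "target_gene": gene,
                    "enhancer_id": f"E{gene}_{j}",
                }
            )
    return promoters, pd.DataFrame(rows)


def _region_ids(gene: str, enhancer_map: pd.DataFrame, j: int) -> tuple[str, str]:
    row = enhancer_map[
        (enhancer_map.target_gene == gene)
    ].iloc[j]
    element = f"enh:{row.enhancer_id}:{gene}"
    return f"{element}:0", element


def generate_planted_grn(
    config: FixtureConfig, enhancer_map: pd.DataFrame
) -> tuple[list[str], list[str], list[str], dict[str, PlantedRegulation], set[frozenset]]:
    """Sample a planted core network over identity TFs and co-factors.

    Every co-factor regulates and is regulated by at least one identity TF;
    each region holds at most its slot capacity of clusters; AND pairs get a
    PPI record. Returns (identity, cofactors, outsiders, regulations, ppi).
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = _gene_names(config.n_tfs)
    order = [str(g) for g in rng.permutation(genes)]
    identity = sorted(order[: config.n_identity])
    cofactors = sorted(order[config.n_identity : config.n_identity + config.n_cofactors])
    outsiders = sorted(order[config.n_identity + config.n_cofactors :])
    core = identity + cofactors
    enh_counts = {
        g: int((enhancer_map.target_gene == g).sum()) for g in genes
    }
    # per-target flat slot lists: ("promoter", None) x4 then ("enhancer", j) x2
    regs: dict[str, list[tuple[str, int | None, str]]] = {t: [] for t in core}

    def capacity(t: str) -> int:
        return PROMOTER_SLOTS + ENHANCER_SLOTS * min(2, enh_counts[t])

    def add_regulator(target: str, tf: str) -> bool:
        existing = [r[2] for r in regs[target]]
        if tf in existing or len(regs[target]) >= capacity(target):
            return False
        n_prom = sum(1 for r in regs[target] if r[0] == "promoter")
        if n_prom < PROMOTER_SLOTS and (rng.random() < 0.7 or enh_counts[target] == 0):
            regs[target].append(("promoter", None, tf))
            return True
        for j in range(min(2, enh_counts[target])):
            n_in = sum(1 for r in regs[target] if r[0] == "enhancer" and r[1] == j)
            if n_in < ENHANCER_SLOTS:
                regs[target].append(("enhancer", j, tf))
                return True
        if n_prom < PROMOTER_SLOTS:
            regs[target].append(("promoter", None, tf))
            return True
        return False

    # co-factor constraints first: c -> identity and identity -> c
    for idx, c in enumerate(cofactors):
        tgt = identity[idx % len(identity)]
        if not add_regulator(tgt, c):
            raise RuntimeError("could not place mandatory co-factor edge")
        src = identity[int(rng.integers(len(identity)))]
        if not add_regulator(c, src):
            raise RuntimeError("could not place mandatory identity edge")
    # random extra regulation among core TFs (self-loops allowed, rare)
    for t in core:
        want = int(rng.integers(1, 4))
        base = len(regs[t])
        pool = list(rng.permutation(core))
        for tf in pool:
            if len(regs[t]) >= base + want or len(regs[t]) >= capacity(t):
                break
            if tf == t and rng.random() > 0.15:
                continue
            add_regulator(t, tf)

    ppi: set[frozenset] = set()
    regulations: dict[str, PlantedRegulation] = {}
    for t in core:
        prom_tfs = sorted(r[2] for r in regs[t] if r[0] == "promoter")
        by_enh: dict[int, list[str]] = {}
        for kind, j, tf in regs[t]:
            if kind == "enhancer":
                by_enh.setdefault(j, []).append(tf)

        def make_clusters(tfs: list[str]) -> list[frozenset]:
            tfs = sorted(tfs)
            clusters: list[frozenset] = []
            i = 0
            while i < len(tfs):
                if i + 1 < len(tfs) and rng.random() < 0.4:
                    pair = frozenset(tfs[i : i + 2])
                    clusters.append(pair)
                    ppi.add(pair)
                    i += 2
                else:
                    clusters.append(frozenset([tfs[i]]))
                    i += 1
            return sorted(clusters, key=min)

        regulations[t] = PlantedRegulation(
            target=t,
            promoter_clusters=make_clusters(prom_tfs),
            enhancer_clusters={
                j: make_clusters(tfs) for j, tfs in sorted(by_enh.items())
            },
        )
    # decoy PPIs between TFs that never co-bind a region (tests conjunction)
    if len(outsiders) >= 2:
        ppi.add(frozenset(outsiders[:2]))
    return identity, cofactors, outsiders, regulations, ppi


def _active_segment(enh_row) -> tuple[int, int]:
    """Planted H3K27ac truncation: the enhancer minus 100 bp at both ends."""
    return int(enh_row.start) + 100, int(enh_row.end) - 100


def generate_celltype_peaks(
    config: FixtureConfig,
    promoters: list[PromoterAnnotation],
    enhancer_map: pd.DataFrame,
    regulations: dict[str, PlantedRegulation],
    celltype: str = "target",
    inactive_genes: set[str] | None = None,
) -> dict:
    """Emit H3K4me3/H3K27ac/DNase/TF peaks realizing the planted network.

    At zero noise the reconstruction rules recover exactly the planted
    edges: every planted binding gets a TF peak in a fixed slot of the
    active, accessible region; AND-pair peaks reciprocally overlap by 0.8;
    singleton co-occupants are disjoint. ``inactive_genes`` (initial cell
    type of a conversion scenario) get none of their regions activated.
    """
    if celltype not in ("initial", "target"):
        raise ValueError(f"celltype must be initial|target, got {celltype!r}")
    inactive = inactive_genes or set()
    prom_by_gene = {p.gene: p for p in promoters}
    h3k4me3: list[GenomicInterval] = []
    h3k27ac: list[GenomicInterval] = []
    dnase: list[GenomicInterval] = []
    tf_peaks: dict[str, list[GenomicInterval]] = {}

    def place_clusters(
        clusters: list[frozenset], region_start: int, region_end: int
    ) -> None:
        pos = region_start + 100
        for cl in clusters:
            members = sorted(cl)
            if pos + SLOT_WIDTH + PAIR_SHIFT * (len(members) - 1) > region_end:
                raise RuntimeError("region slot overflow; planted spec inconsistent")
            for m, tf in enumerate(members):
                s = pos + m * PAIR_SHIFT
                tf_peaks.setdefault(tf, []).append(
                    GenomicInterval(CHROM, s, s + SLOT_WIDTH)
                )
            pos += SLOT_STRIDE

    for gene, reg in sorted(regulations.items()):
        if gene in inactive:
            continue
        ann = prom_by_gene[gene]
        window = define_promoter(ann)
        h3k4me3.append(GenomicInterval(CHROM, ann.tss - 200, ann.tss + 200))
        dnase.append(GenomicInterval(CHROM, window.start, window.end))
        place_clusters(reg.promoter_clusters, window.start, window.end)
        gene_enh = enhancer_map[enhancer_map.target_gene == gene].reset_index(drop=True)
        for j, clusters in sorted(reg.enhancer_clusters.items()):
            row = gene_enh.iloc[j]
            seg_start, seg_end = _active_segment(row)
            h3k27ac.append(GenomicInterval(CHROM, seg_start, seg_end))
            dnase.append(GenomicInterval(CHROM, seg_start, seg_end))
            place_clusters(clusters, seg_start, seg_end)

    if config.noise_level > 0:
        rng = np.random.default_rng(config.seed + (7 if celltype == "target" else 8))
        glen = config.genome_length or (10_000 + config.n_tfs * GENE_SPACING)

        def perturb(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
            kept = [iv for iv in ivs if rng.random() >= config.noise_level]
            extra = rng.poisson(config.noise_level * max(1, len(ivs)))
            for _ in range(extra):
                s = int(rng.integers(0, glen - 400))
                kept.append(GenomicInterval(CHROM, s, s + 400))
            return kept

        h3k4me3 = perturb(h3k4me3)
        h3k27ac = perturb(h3k27ac)
        dnase = perturb(dnase)
        tf_peaks = {tf: perturb(ivs) for tf, ivs in tf_peaks.items()}

    return {
        "H3K4me3": PeakSet("H3K4me3", h3k4me3, source=f"{celltype}:synthetic"),
        "H3K27ac": PeakSet("H3K27ac", h3k27ac, source=f"{celltype}:synthetic"),
        "DNase": PeakSet("DNase", dnase, source=f"{celltype}:synthetic"),
        "tf": {
            tf: PeakSet(f"TF-binding:{tf}", ivs, source=f"{celltype}:synthetic")
            for tf, ivs in sorted(tf_peaks.items())
        },
    }


def generate_expression_compendium(
    config: FixtureConfig,
    identity: list[str],
    cofactors: list[str],
    outsiders: list[str],
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Background compendium plus query profile with planted roles.

    Identity TFs: 100 in the query, 0 in the background. Co-factors: 80 in
    the query, one strong background bump (100) in a dedicated sample, 5
    elsewhere. Outsiders: 0 in the query, broad background expression with
    a home-phenotype elevation. Returns (values, phenotypes, query).
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = identity + cofactors + outsiders
    n_bg = config.n_background_samples
    samples = [f"S{j:03d}" for j in range(1, n_bg + 1)]
    phenotypes = pd.Series(
        [f"phen{j % config.n_phenotypes}" for j in range(n_bg)], index=samples
    )
    values = pd.DataFrame(0.0, index=genes, columns=samples)
    for c_idx, c in enumerate(cofactors):
        values.loc[c] = 5.0
        values.loc[c, samples[c_idx]] = 100.0  # the related-sample bump
    for o_idx, o in enumerate(outsiders):
        base = 20.0 + 5.0 * rng.random(n_bg)
        home = f"phen{o_idx % config.n_phenotypes}"
        bump = np.where(phenotypes.values == home, 30.0, 0.0)
        values.loc[o] = base + bump
    if config.noise_level > 0:
        jitter = rng.normal(0.0, config.noise_level, size=values.shape)
        values = (values * (1.0 + jitter)).clip(lower=0.0)
    query = pd.Series(0.0, index=genes)
    query[identity] = 100.0
    query[cofactors] = 80.0
    return values, phenotypes, query


def _planted_rules(
    regulations: dict[str, PlantedRegulation], enhancer_map: pd.DataFrame
) -> dict[str, LogicRule]:
    """Planted logic rules with the region ids reconstruction will emit."""
    rules = {}
    for t, reg in regulations.items():
        prom = RegionClause(region_id=f"prom:{t}", clusters=list(reg.promoter_clusters))
        gene_enh = enhancer_map[enhancer_map.target_gene == t].reset_index(drop=True)
        enh_clauses = []
        for j, clusters in sorted(reg.enhancer_clusters.items()):
            row = gene_enh.iloc[j]
            enh_clauses.append(
                RegionClause(
                    region_id=f"enh:{row.enhancer_id}:{t}:0", clusters=list(clusters)
                )
            )
        rules[t] = LogicRule(
            target=t, promoter_clause=prom, enhancer_clauses=enh_clauses
        )
    return rules


def _planted_edges(regulations: dict[str, PlantedRegulation]) -> set[tuple[str, str]]:
    return {
        (tf, t) for t, reg in regulations.items() for tf in reg.regulators
    }


def generate_fixture_bundle(config: FixtureConfig) -> FixtureBundle:
    """Full reconstruction fixture: genome, peaks, compendium, PPI, truth."""
    promoters, enhancer_map = generate_toy_genome(config)
    identity, cofactors, outsiders, regulations, ppi = generate_planted_grn(
        config, enhancer_map
    )
    target_peaks = generate_celltype_peaks(
        config, promoters, enhancer_map, regulations, "target"
    )
    initial_peaks = generate_celltype_peaks(
        config, promoters, enhancer_map, regulations, "initial"
    )
    values, phenotypes, query = generate_expression_compendium(
        config, identity, cofactors, outsiders
    )
    return FixtureBundle(
        config=config,
        promoters=promoters,
        enhancer_map=enhancer_map,
        target_peaks=target_peaks,
        initial_peaks=initial_peaks,
        compendium=values,
        phenotypes=phenotypes,
        query_profile=query,
        initial_profile=None,
        ppi=ppi,
        identity_tfs=identity,
        cofactors=cofactors,
        outsiders=outsiders,
        regulations=regulations,
        planted_edges=_planted_edges(regulations),
        planted_rules=_planted_rules(regulations, enhancer_map),
    )


def generate_conversion_scenario(config: FixtureConfig) -> FixtureBundle:
    """Conversion scenario with a planted optimal IF set and essential TF.

    The planted network is a regulatory cascade TF01 -> TF02 -> ... in which
    TF01 has no incoming edges (self-maintaining) and is silent in the
    initial cell type, so no perturbation omitting it can ever activate the
    whole network (T = 0). The planted optimal set is the first ``k = 3``
    cascade genes: their regions are the only ones inactive in the initial
    epigenome, so perturbing exactly them yields E = 1, and clamping TF01
    activates every gene from any initial state (T = 1); every other size-k
    set scores strictly below 1.
    """
    promoters, enhancer_map = generate_toy_genome(config)
    genes = _gene_names(config.n_tfs)
    regulations: dict[str, PlantedRegulation] = {
        genes[0]: PlantedRegulation(target=genes[0])  # essential: no regulators
    }
    for i in range(1, len(genes)):
        regulations[genes[i]] = PlantedRegulation(
            target=genes[i],
            promoter_clusters=[frozenset([genes[i - 1]])],
        )
    optimal = tuple(genes[:3])
    target_peaks = generate_celltype_peaks(
        config, promoters, enhancer_map, regulations, "target"
    )
    initial_peaks = generate_celltype_peaks(
        config,
        promoters,
        enhancer_map,
        regulations,
        "initial",
        inactive_genes=set(optimal),
    )
    rng = np.random.default_rng(config.seed + 3)
    n_bg = config.n_background_samples
    samples = [f"S{j:03d}" for j in range(1, n_bg + 1)]
    values = pd.DataFrame(
        10.0 + 5.0 * rng.random((len(genes), n_bg)), index=genes, columns=samples
    )
    phenotypes = pd.Series("background", index=samples)
    initial_profile = pd.Series(0.0, index=genes)
    # essential TF silent initially; the rest sit mid-background (marginal ~ 0.5)
    for g in genes[1:]:
        initial_profile[g] = float(np.median(values.loc[g]))
    query = pd.Series(100.0, index=genes)
    return FixtureBundle(
        config=config,
        promoters=promoters,
        enhancer_map=enhancer_map,
        target_peaks=target_peaks,
        initial_peaks=initial_peaks,
        compendium=values,
        phenotypes=phenotypes,
        query_profile=query,
        initial_profile=initial_profile,
        ppi=set(),
        identity_tfs=list(genes),
        cofactors=[],
        outsiders=[],
        regulations=regulations,
        planted_edges=_planted_edges(regulations),
        planted_rules=_planted_rules(regulations, enhancer_map),
        optimal_set=optimal,
        essential_tf=genes[0],
        k=3,
    )


def random_boolean_model(n: int, rng: np.random.Generator):
    """Random compiled Boolean network for dynamics stress tests.

    Each node gets a promoter clause of 1-2 clusters over random regulators
    and, with probability 0.5, one enhancer clause; ~15% of nodes are
    self-maintaining.
    """
    from .scoring import compile_model

    tfs = _gene_names(n)
    rules: dict[str, LogicRule] = {}
    for t in tfs:
        if rng.random() < 0.15:
            rules[t] = LogicRule(target=t)
            continue

        def rand_clause(rid: str) -> RegionClause:
            n_clusters = int(rng.integers(1, 3))
            clusters = []
            for _ in range(n_clusters):
                size = int(rng.integers(1, 3))
                members = rng.choice(tfs, size=size, replace=False)
                clusters.append(frozenset(str(m) for m in members))
            return RegionClause(region_id=rid, clusters=sorted(clusters, key=min))

        enh = [rand_clause(f"e:{t}")] if rng.random() < 0.5 else []
        rules[t] = LogicRule(
            target=t, promoter_clause=rand_clause(f"p:{t}"), enhancer_clauses=enh
        )
    return compile_model(tfs, rules)
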