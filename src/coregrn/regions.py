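"""Active promoter/enhancer calling and DNase-filtered binding events.

Promoters are fixed windows around annotated TSSs (1500 bp upstream, 500 bp
downstream by default, strand-aware) and are active when they overlap at
least one H3K4me3 peak; the window is kept whole. Annotated enhancers are
active where they intersect H3K27ac peaks, and are truncated to those
intersections: every maximal segment of enhancer ∩ (union of overlapping
peaks) becomes one active region, so two disjoint peaks inside one enhancer
yield two regions. Enhancers with no H3K27ac support are discarded.

A binding event requires a triple overlap of at least 1 bp: TF peak ∩ active
region ∩ some DNase peak, i.e. the contacted bases must lie in accessible
chromatin inside the region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, PeakSet, overlap_length

__all__ = [
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
    "PromoterAnnotation",
    "RegulatoryRegion",
    "BindingEvent",
    "read_promoter_annotation",
    "read_enhancer_map",
    "define_promoter",
    "call_active_promoters",
    "call_active_enhancers",
    "call_binding_events",
    "regions_to_frame",
]

#: Promoter window relative to the TSS, in bp.
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class PromoterAnnotation:
    gene: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("promoter strand must be '+' or '-'")


@dataclass
class RegulatoryRegion:
    """An active (or candidate) regulatory region of one target gene.

    ``region_id`` is unique per region; ``element_id`` names the annotated
    element the region derives from (promoter gene or enhancer id + gene) and
    is shared by all segments of one truncated enhancer, so that regions can
    be matched across cell types.
    """

    region_id: str
    gene: str
    kind: str  # promoter | enhancer
    interval: GenomicInterval
    active: bool
    element_id: str = ""
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("promoter", "enhancer"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not self.element_id:
            self.element_id = self.region_id


@dataclass(frozen=True)
class BindingEvent:
    tf: str
    target_gene: str
    region_id: str
    peak: GenomicInterval

    @property
    def event_id(self) -> str:
        return f"{self.tf}@{self.region_id}:{self.peak.start}-{self.peak.end}"


def read_promoter_annotation(path: str | Path) -> list[PromoterAnnotation]:
    """TSV with header columns gene, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    return [
        PromoterAnnotation(
            gene=str(r.gene), chrom=str(r.chrom), tss=int(r.tss), strand=str(r.strand)
        )
        for r in df.itertuples()
    ]


def read_enhancer_map(path: str | Path) -> pd.DataFrame:
    """TSV with header columns chrom, start, end, target_gene, enhancer_id."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "target_gene", "enhancer_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enhancer map missing columns: {sorted(missing)}")
    return df


def define_promoter(
    annotation: PromoterAnnotation,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at 0."""
    if annotation.strand == "+":
        start, end = annotation.tss - upstream, annotation.tss + downstream
    else:
        start, end = annotation.tss - downstream, annotation.tss + upstream
    return GenomicInterval(
        chrom=annotation.chrom, start=max(0, start), end=end, strand=annotation.strand
    )


def _peak_tree(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _overlapping(trees: dict[str, IntervalTree], iv: GenomicInterval):
    tree = trees.get(iv.chrom)
    if tree is None:
        return []
    return sorted(tree.overlap(iv.start, iv.end), key=lambda h: (h.begin, h.end))


def call_active_promoters(
    promoters: list[PromoterAnnotation],
    h3k4me3: PeakSet,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[RegulatoryRegion]:
    """One promoter region per gene; active iff >= 1 bp H3K4me3 overlap.

    Promoter coordinates are never truncated to the peaks.
    """
    trees = _peak_tree(h3k4me3)
    out = []
    for ann in promoters:
        window = define_promoter(ann, upstream, downstream)
        hits = _overlapping(trees, window)
        out.append(
            RegulatoryRegion(
                region_id=f"prom:{ann.gene}",
                gene=ann.gene,
                kind="promoter",
                interval=window,
                active=bool(hits),
                element_id=f"prom:{ann.gene}",
                provenance=[f"H3K4me3:{h.data}" for h in hits],
            )
        )
    return out


def call_active_enhancers(
    enhancer_map: pd.DataFrame, h3k27ac: PeakSet
) -> list[RegulatoryRegion]:
    """Active enhancer segments: enhancer ∩ union of overlapping H3K27ac peaks.

    Each maximal covered segment becomes one region; enhancers with no
    overlapping peak are dropped.
    """
    trees = _peak_tree(h3k27ac)
    out = []
    for row in enhancer_map.itertuples():
        enh = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        hits = _overlapping(trees, enh)
        if not hits:
            continue
        # merge clipped peak spans into maximal segments
        spans = sorted(
            (max(enh.start, h.begin), min(enh.end, h.end)) for h in hits
        )
        segments: list[list[int]] = []
        for s, e in spans:
            if segments and s <= segments[-1][1]:
                segments[-1][1] = max(segments[-1][1], e)
            else:
                segments.append([s, e])
        element = f"{row.enhancer_id}:{row.target_gene}"
        for k, (s, e) in enumerate(segments):
            out.append(
                RegulatoryRegion(
                    region_id=f"enh:{element}:{k}",
                    gene=str(row.target_gene),
                    kind="enhancer",
                    interval=GenomicInterval(enh.chrom, s, e),
                    active=True,
                    element_id=f"enh:{element}",
                    provenance=[f"H3K27ac:{h.data}" for h in hits],
                )
            )
    return out


def call_binding_events(
    regions: list[RegulatoryRegion],
    tf_peaks: dict[str, PeakSet],
    dnase: PeakSet,
) -> list[BindingEvent]:
    """Emit one event per (tf, region, peak) with a >= 1 bp triple overlap.

    The accessible base(s) must lie inside the TF-peak ∩ region intersection:
    a DNase site elsewhere in the region (or under the peak but outside the
    region) does not license the event.
    """
    dnase_trees = _peak_tree(dnase)
    events: list[BindingEvent] = []
    for region in regions:
        if not region.active:
            continue
        for tf in sorted(tf_peaks):
            for peak in tf_peaks[tf]:
                if overlap_length(peak, region.interval) < 1:
                    continue
                core = GenomicInterval(
                    peak.chrom,
                    max(peak.start, region.interval.start),
                    min(peak.end, region.interval.end),
                )
                if any(
                    overlap_length(core, h.data) >= 1
                    for h in _overlapping(dnase_trees, core)
                ):
                    events.append(
                        BindingEvent(
                            tf=tf,
                            target_gene=region.gene,
                            region_id=region.region_id,
                            peak=peak,
                        )
                    )
    return events


def regions_to_frame(regions: list[RegulatoryRegion]) -> pd.DataFrame:
    """Export regions as a stable-id TSV-ready table."""
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "element_id": [r.element_id for r in regions],
            "gene": [r.gene for r in regions],
            "kind": [r.kind for r in regions],
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "active": [r.active for r in regions],
        }
    )
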