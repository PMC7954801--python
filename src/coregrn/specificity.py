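"""Identity-TF ranking, activity calls and co-factor rank statistics.

The identity of a cell type is carried by transcription factors whose
expression is maximally specific to it. Specificity is measured against a
background compendium of many phenotypes: for each TF the empirical
distribution of its expression over {query} + background samples is compared
with the idealized distribution that puts all mass on the query sample, using
the base-2 Jensen-Shannon divergence. A TF expressed exclusively in the query
has divergence 0; we report

    specificity = 1 - sqrt(JSD)   in [0, 1]

so that 1 means perfectly query-specific. Background samples too similar to
the query (Pearson r above a cutoff, 0.75 by default) are excluded first, so
that related cell types do not mask genuinely specific factors.

Activity of a gene is decided by an empirical one-sided test of the null
hypothesis that the gene is inactive, against the gene's own background
distribution: p = (1 + #{background >= x}) / (1 + N), significant below 0.1.
The activation probability used by the state prior is the empirical CDF
P(active) = #{background < x} / N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

__all__ = [
    "DEFAULT_CORRELATION_CUTOFF",
    "DEFAULT_ACTIVITY_ALPHA",
    "DEFAULT_COFACTOR_Z",
    "ExpressionCompendium",
    "SpecificityResult",
    "ActivityCall",
    "CofactorZscore",
    "read_query_profile",
    "calibrate_correlation_cutoff",
    "filter_correlated_samples",
    "specificity_score",
    "specificity_profile",
    "select_identity_tfs",
    "activity_pvalue",
    "call_activity",
    "activation_probability",
    "cofactor_rank_zscore",
    "compendium_rank_zscores",
]

#: Pearson cutoff for excluding query-like background samples.
DEFAULT_CORRELATION_CUTOFF = 0.75
#: Significance level of the inactivity test.
DEFAULT_ACTIVITY_ALPHA = 0.1
#: Rank z-score bound for co-factor eligibility.
DEFAULT_COFACTOR_Z = -1.5


@dataclass
class ExpressionCompendium:
    """Gene x sample non-negative abundance table with phenotype labels.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``phenotypes`` maps sample id -> free-text phenotype label.
    """

    values: pd.DataFrame
    phenotypes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and sample identifiers must be unique")
        if self.phenotypes is None:
            self.phenotypes = pd.Series("unknown", index=self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, keep: list[str]) -> "ExpressionCompendium":
        return ExpressionCompendium(
            values=self.values[keep], phenotypes=self.phenotypes[keep]
        )

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, metadata_path: str | Path | None = None
    ) -> "ExpressionCompendium":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        phen = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
            phen = meta.iloc[:, 0].reindex(values.columns)
        return cls(values=values, phenotypes=phen)

    def to_tsv(
        self, matrix_path: str | Path, metadata_path: str | Path | None = None
    ) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        if metadata_path is not None:
            self.phenotypes.rename("phenotype").to_frame().to_csv(
                metadata_path, sep="\t", index_label="sample"
            )


@dataclass(frozen=True)
class SpecificityResult:
    tf: str
    specificity: float
    rank: int


@dataclass(frozen=True)
class ActivityCall:
    gene: str
    p_inactive: float
    active: bool
    p_active_marginal: float


@dataclass(frozen=True)
class CofactorZscore:
    tf: str
    rank_query: int
    rank_mean: float
    rank_sd: float
    z: float

    @property
    def eligible(self) -> bool:
        return self.z <= DEFAULT_COFACTOR_Z


def read_query_profile(path: str | Path) -> pd.Series:
    """Read a 2-column (gene, value) TSV into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "value"])
    return pd.Series(df["value"].values, index=df["gene"].values, dtype=float)


def _log_transform(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def calibrate_correlation_cutoff(
    compendium: ExpressionCompendium, labels: pd.Series | dict
) -> float:
    """Pick the correlation cutoff that best separates in-class samples.

    Samples are classified as in-class when their Pearson correlation (on
    log2(x+1) values) to the in-class centroid is at least the cutoff; the
    cutoff maximizing the F1 score over a 0.01-step grid on [0, 1] is
    returned, ties broken toward the larger value.
    """
    labels = pd.Series(labels).reindex(compendium.samples)
    if labels.isna().any():
        raise ValueError("labels must cover every compendium sample")
    y = labels.astype(bool).values
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")
    logx = _log_transform(compendium.values.values)
    centroid = logx[:, y].mean(axis=1)
    r = np.array([_pearson(logx[:, j], centroid) for j in range(logx.shape[1])])
    best_cut, best_f1 = 0.0, -1.0
    for cut in np.arange(0.0, 1.0 + 1e-9, 0.01):
        pred = r >= cut
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        fn = int((~pred & y).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 >= best_f1:  # >= : ties go to the larger cutoff
            best_cut, best_f1 = float(cut), f1
    return best_cut


def filter_correlated_samples(
    query: pd.Series,
    compendium: ExpressionCompendium,
    cutoff: float = DEFAULT_CORRELATION_CUTOFF,
) -> ExpressionCompendium:
    """Drop background samples correlated with the query above ``cutoff``.

    Correlation is Pearson on log2(x+1) over the genes shared between query
    and compendium. Idempotent; never sees (hence never removes) the query.
    """
    shared = [g for g in compendium.genes if g in query.index]
    if len(shared) < 2:
        raise ValueError("need >= 2 shared genes to compute correlation")
    q = _log_transform(query[shared].values)
    mat = _log_transform(compendium.values.loc[shared].values)
    keep = [
        s
        for j, s in enumerate(compendium.samples)
        if _pearson(mat[:, j], q) <= cutoff
    ]
    return compendium.subset_samples(keep)


def _specificity_from_matrix(values: np.ndarray, query_col: int = 0) -> np.ndarray:
    """Per-gene specificity for a gene x sample block; query at ``query_col``.

    Genes with zero total expression get specificity NaN (undefined).
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    totals = values.sum(axis=1)
    out = np.full(n_genes, np.nan)
    ideal = np.zeros(n_samples)
    ideal[query_col] = 1.0
    ok = totals > 0
    if ok.any():
        p = values[ok] / totals[ok, None]
        # jensenshannon returns sqrt(JSD); base 2 bounds it in [0, 1]
        d = jensenshannon(p, ideal[None, :], base=2, axis=1)
        out[ok] = 1.0 - np.nan_to_num(d, nan=0.0)
    return out


def specificity_score(
    tf: str, query: pd.Series, filtered: ExpressionCompendium
) -> float:
    """Specificity of one TF: 1 - sqrt(base-2 JSD to the query point mass)."""
    if tf not in query.index or tf not in filtered.values.index:
        raise KeyError(f"{tf} missing from query or compendium")
    row = np.concatenate(
        [[float(query[tf])], filtered.values.loc[tf].values.astype(float)]
    )
    if row.sum() <= 0:
        raise ValueError(f"{tf} has all-zero expression; specificity undefined")
    return float(_specificity_from_matrix(row[None, :], query_col=0)[0])


def specificity_profile(
    query: pd.Series,
    filtered: ExpressionCompendium,
    candidates: list[str] | None = None,
) -> pd.Series:
    """Specificity for every candidate gene (NaN where undefined)."""
    genes = candidates if candidates is not None else filtered.genes
    missing = [g for g in genes if g not in filtered.values.index or g not in query.index]
    if missing:
        raise KeyError(f"genes missing from query/compendium: {missing[:5]}")
    block = np.column_stack(
        [query[genes].values.astype(float), filtered.values.loc[genes].values]
    )
    return pd.Series(_specificity_from_matrix(block, query_col=0), index=genes)


def select_identity_tfs(
    query: pd.Series,
    compendium: ExpressionCompendium,
    n: int = 10,
    candidates: list[str] | None = None,
) -> list[SpecificityResult]:
    """Top-``n`` TFs by specificity, ties broken lexicographically on gene id.

    ``compendium`` should already be correlation-filtered. Genes with
    undefined specificity (all-zero) rank last.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = specificity_profile(query, compendium, candidates)
    scored = sorted(
        spec.items(), key=lambda kv: (-(kv[1] if np.isfinite(kv[1]) else -1.0), kv[0])
    )
    if n > len(scored):
        warnings.warn(
            f"requested {n} identity TFs but only {len(scored)} candidates; "
            "returning all"
        )
        n = len(scored)
    return [
        SpecificityResult(tf=g, specificity=float(s), rank=i + 1)
        for i, (g, s) in enumerate(scored[:n])
    ]


def activity_pvalue(x: float, background: np.ndarray) -> float:
    """One-sided empirical p for the null that the gene is inactive.

    p = (1 + #{background >= x}) / (1 + N); the +1 correction keeps p > 0.
    """
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    return float((1 + int((background >= x).sum())) / (1 + background.size))


def activation_probability(x: float, background: np.ndarray) -> float:
    """Empirical CDF P(active) = #{background < x} / N."""
    background = np.asarray(background, dtype=float)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    return float(int((background < x).sum()) / background.size)


def call_activity(
    query: pd.Series,
    compendium: ExpressionCompendium,
    alpha: float = DEFAULT_ACTIVITY_ALPHA,
    pvalue_override: dict[str, float] | None = None,
) -> dict[str, ActivityCall]:
    """Activity calls and activation probabilities for every query gene.

    The background of each gene is its own row of the compendium.
    ``pvalue_override`` allows externally computed inactivity p-values to
    replace the empirical surrogate per gene.
    """
    calls: dict[str, ActivityCall] = {}
    for gene in query.index:
        if gene not in compendium.values.index:
            continue
        bg = compendium.values.loc[gene].values
        x = float(query[gene])
        p = activity_pvalue(x, bg)
        if pvalue_override and gene in pvalue_override:
            p = float(pvalue_override[gene])
        calls[gene] = ActivityCall(
            gene=gene,
            p_inactive=p,
            active=p < alpha,
            p_active_marginal=activation_probability(x, bg),
        )
    return calls


def cofactor_rank_zscore(
    tf: str, rank_query: int, background_ranks: np.ndarray
) -> CofactorZscore:
    """Standardize the query-sample specificity rank of a TF.

    z = (rank_query - mean) / sd of the TF's ranks across background samples.
    Lower rank = more specific, so z <= -1.5 flags query enrichment. A
    degenerate sd of 0 yields z = 0 (never eligible) unless the query rank
    beats the constant background rank, which yields z = -inf.
    """
    background_ranks = np.asarray(background_ranks, dtype=float)
    if background_ranks.size < 2:
        raise ValueError("need >= 2 background rank observations")
    mean = float(background_ranks.mean())
    sd = float(background_ranks.std(ddof=0))
    if sd == 0:
        z = float("-inf") if rank_query < mean else 0.0
    else:
        z = (rank_query - mean) / sd
    return CofactorZscore(
        tf=tf, rank_query=rank_query, rank_mean=mean, rank_sd=sd, z=z
    )


def _rank_vector(spec: pd.Series) -> pd.Series:
    """Competition-free dense ranks: 1 = most specific; NaN ranks last;
    ties broken lexicographically on gene id for determinism."""
    order = sorted(
        spec.index, key=lambda g: (-(spec[g] if np.isfinite(spec[g]) else -1.0), g)
    )
    return pd.Series({g: i + 1 for i, g in enumerate(order)})


def compendium_rank_zscores(
    query: pd.Series,
    filtered: ExpressionCompendium,
    candidates: list[str] | None = None,
) -> dict[str, CofactorZscore]:
    """Rank z-scores of every candidate TF against per-sample rankings.

    Each background sample of the filtered compendium is treated in turn as
    the query (ranked against the remaining filtered samples plus the true
    query-free background); the resulting rank distribution standardizes the
    real query's rank.
    """
    genes = candidates if candidates is not None else filtered.genes
    query_ranks = _rank_vector(specificity_profile(query, filtered, genes))
    bg_ranks = []
    mat = filtered.values.loc[genes]
    for j, s in enumerate(filtered.samples):
        rest = filtered.subset_samples([x for x in filtered.samples if x != s])
        spec = specificity_profile(mat[s], rest, genes)
        bg_ranks.append(_rank_vector(spec))
    bg = pd.DataFrame(bg_ranks)  # samples x genes
    return {
        g: cofactor_rank_zscore(g, int(query_ranks[g]), bg[g].values) for g in genes
    }
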