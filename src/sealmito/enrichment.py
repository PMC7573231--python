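"""DE-gene filtering and gene-set enrichment.

Implements the strict fold-change/adjusted-p filter, one-sided Fisher
exact enrichment against a GMT-style collection, Benjamini-Hochberg
adjustment, a permutation-based rank-deviation z-score, and the combined
score ``-ln(p) x z``.

Sign convention: the rank-deviation z is (expected rank - observed
rank) / sd(rank), so enriched sets (ranked better, i.e. lower, than
expected) have positive z, and the combined score -ln(p) x z is positive
for enriched sets with small p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "filter_de",
    "fisher_enrich",
    "bh_adjust",
    "combined_score",
    "rank_deviation_z",
    "enrich",
]

DE_COLUMNS = ("gene_id", "log2fc", "padj")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT semantics: name, description, members)."""

    names: tuple[str, ...]
    descriptions: tuple[str, ...]
    members: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("gene-set names must be unique")
        if any(not m for m in self.members):
            raise ValidationError("gene sets must be non-empty")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_dict(cls, sets: dict[str, set[str] | list[str]]) -> "GeneSetCollection":
        names = tuple(sets)
        return cls(
            names=names,
            descriptions=tuple("" for _ in names),
            members=tuple(frozenset(sets[n]) for n in names),
        )


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    background_size: int
    odds_ratio: float
    p: float
    padj: float = math.nan
    z: float = math.nan
    combined_score: float = math.nan


def _validate_de(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"DE table missing columns {missing}")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].unique()
        raise ValidationError(f"duplicate gene ids: {list(dupes[:5])}")
    padj = table["padj"].to_numpy(dtype=float)
    finite = padj[np.isfinite(padj)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValidationError("padj values must lie in [0, 1]")
    return table


def filter_de(
    table: pd.DataFrame, padj_cut: float = 0.05, lfc_cut: float = 1.0
) -> tuple[list[str], list[str]]:
    """Strict DE filter: (upregulated genes, downregulated genes).

    up: padj < padj_cut and log2fc > lfc_cut; down: padj < padj_cut and
    log2fc < -lfc_cut.  All inequalities strict, so padj == 0.05 or
    |log2fc| == 1 are excluded at the default cuts.
    """
    table = _validate_de(table)
    padj = table["padj"].to_numpy(dtype=float)
    lfc = table["log2fc"].to_numpy(dtype=float)
    sig = padj < padj_cut
    up = table.loc[sig & (lfc > lfc_cut), "gene_id"].tolist()
    down = table.loc[sig & (lfc < -lfc_cut), "gene_id"].tolist()
    return up, down


def fisher_enrich(
    query: set[str], target: set[str], background: set[str]
) -> tuple[int, float, float]:
    """One-sided (enrichment) Fisher exact test on the 2x2 overlap table.

    Returns (overlap, odds_ratio, p) where p = P(overlap >= observed)
    under the hypergeometric null.
    """
    if not background:
        raise ValidationError("background gene set is empty")
    query = set(query) & set(background)
    target = set(target) & set(background)
    n_bg, n_q, n_t = len(background), len(query), len(target)
    k = len(query & target)
    a, b = k, n_q - k
    c, d = n_t - k, n_bg - n_q - n_t + k
    odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
    # one-sided 'greater' Fisher p == hypergeometric survival at k-1
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_t, n_q))
    return k, odds, min(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def combined_score(p: float, z: float) -> float:
    """Enrichment ranking score: -ln(p) x z.

    Positive for enriched sets (small p, positive z).  p == 0 is capped
    at the smallest positive normal float with a warning.
    """
    if p < 0 or p > 1:
        raise ValidationError(f"p must be in [0, 1], got {p}")
    if p == 0:
        warnings.warn(
            "p == 0 capped at the smallest positive float", UserWarning, stacklevel=2
        )
        p = float(np.finfo(float).tiny)
    return -math.log(p) * z


def _fisher_p_matrix(
    member_matrix: np.ndarray, set_sizes: np.ndarray, query_mask: np.ndarray
) -> np.ndarray:
    """Vectorized one-sided Fisher p for every set against one query."""
    n_bg = query_mask.size
    n_q = int(query_mask.sum())
    overlaps = member_matrix @ query_mask
    return stats.hypergeom.sf(overlaps - 1, n_bg, set_sizes, n_q)


def rank_deviation_z(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Per-set z-score of the deviation of each set's p-value rank from
    its expected rank under random queries.

    For each set, the rank (1 = smallest p, ties get mean rank) of its
    Fisher p among all sets is compared against the distribution of that
    rank over ``n_permutations`` random queries of the same size drawn
    from the background: z = (mean permuted rank - observed rank) / sd.
    Positive z means the set ranks better than expected.  Collections of
    a single set have no rank variation; all z are NaN then.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    bg = sorted(background)
    n_bg = len(bg)
    if n_bg == 0:
        raise ValidationError("background gene set is empty")
    index = {g: i for i, g in enumerate(bg)}
    n_sets = len(collection)
    if n_sets == 1:
        return np.array([math.nan])

    member_matrix = np.zeros((n_sets, n_bg), dtype=float)
    for si, members in enumerate(collection.members):
        for g in members:
            if g in index:
                member_matrix[si, index[g]] = 1.0
    set_sizes = member_matrix.sum(axis=1)

    query_mask = np.zeros(n_bg)
    for g in query:
        if g in index:
            query_mask[index[g]] = 1.0
    n_q = int(query_mask.sum())
    if n_q == 0:
        return np.full(n_sets, math.nan)

    observed_rank = stats.rankdata(
        _fisher_p_matrix(member_matrix, set_sizes, query_mask)
    )

    rng = np.random.default_rng(seed)
    perm_ranks = np.empty((n_permutations, n_sets))
    for i in range(n_permutations):
        mask = np.zeros(n_bg)
        mask[rng.choice(n_bg, size=n_q, replace=False)] = 1.0
        perm_ranks[i] = stats.rankdata(
            _fisher_p_matrix(member_matrix, set_sizes, mask)
        )
    sd = perm_ranks.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (perm_ranks.mean(axis=0) - observed_rank) / sd
    z[sd == 0] = math.nan
    return z


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    n_permutations: int = 1000,
    seed: int | None = None,
    compute_z: bool = True,
) -> list[EnrichmentResult]:
    """Full enrichment of a query against a collection.

    Fisher exact p per set, BH adjustment across sets, optional
    permutation rank-deviation z and combined score.  Results are sorted
    by combined score (descending) when z is computed, else by p.
    """
    background = set(background)
    query = set(query) & background
    stats_per_set = [
        fisher_enrich(query, set(members) & background, background)
        for members in collection.members
    ]
    pvals = bh_adjust([p for _, _, p in stats_per_set])
    if compute_z:
        zs = rank_deviation_z(
            query, collection, background, n_permutations=n_permutations, seed=seed
        )
    else:
        zs = np.full(len(collection), math.nan)

    results = []
    for i, (name, members) in enumerate(zip(collection.names, collection.members)):
        k, odds, p = stats_per_set[i]
        z = float(zs[i])
        score = combined_score(p, z) if math.isfinite(z) else math.nan
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_count=k,
                set_size=len(set(members) & background),
                query_size=len(query),
                background_size=len(background),
                odds_ratio=odds,
                p=p,
                padj=float(pvals[i]),
                z=z,
                combined_score=score,
            )
        )
    if compute_z:
        results.sort(
            key=lambda r: (-(r.combined_score if math.isfinite(r.combined_score) else -math.inf), r.p)
        )
    else:
        results.sort(key=lambda r: r.p)
    return results
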