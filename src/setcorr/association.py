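"""Gene x gene-set Spearman correlation, relative ranks, and ranking queries.

Each gene's fold-change profile is correlated (Spearman) with each gene set's
enrichment-score profile across samples. Because the gene sets overlap
heavily, corrected significance values are hard to interpret; instead every
coefficient is assigned a *relative rank*: the whole rho distribution is
translated to mean 0, coefficients are ranked by the magnitude of their
distance from that center (descending), and the rank is divided by the total
number of finite coefficients. A strong association — positive or negative —
therefore has a relative rank near 0; 0.011 means "in the top 1.1% of all
gene/gene-set pairs".

Directional "down" sets (names matching ``_DN``) are reported with the
opposite correlation sign for interpretability: anticorrelation with a
down-signature means the gene tracks the signature's source process.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import EnrichmentMatrix, enrichment_matrix, loo_enrichment_scores
from .io_formats import ExpressionMatrix
from .preprocess import PreparedGeneSet

DEFAULT_GENE_BLOCK = 1024


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation: Pearson correlation of midranks.

    Ties receive average ranks. Returns NaN (undefined) when either vector is
    constant. Vectors must have equal length >= 3.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    nx2 = rx @ rx
    ny2 = ry @ ry
    if nx2 == 0.0 or ny2 == 0.0:
        return float("nan")
    return float((rx @ ry) / np.sqrt(nx2 * ny2))


def relative_rank_from_position(rank: float, n_total: int) -> float:
    """Relative rank of a coefficient at magnitude-rank ``rank`` among ``n_total``.

    E.g. the 879,685th strongest of 80,705,030 coefficients has relative rank
    879685 / 80705030 ~= 0.011.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return rank / n_total


def center_and_rank(rho: np.ndarray) -> tuple[float, np.ndarray]:
    """Translate the rho distribution to mean 0 and rank magnitudes.

    Returns ``(center, relative_rank)`` where ``center`` is the mean of all
    finite rho and ``relative_rank[i, j] = rank of |rho[i, j] - center| when
    all finite magnitudes are sorted descending (ties averaged), divided by
    the number of finite entries``. The strongest association gets the
    smallest relative rank; non-finite entries stay NaN.
    """
    rho = np.asarray(rho, dtype=np.float64)
    finite = np.isfinite(rho)
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("no finite correlation coefficients")
    center = float(rho[finite].mean())
    magnitude = np.abs(rho[finite] - center)
    ranks = stats.rankdata(-magnitude, method="average")
    relative = np.full(rho.shape, np.nan)
    relative[finite] = relative_rank_from_position(ranks, n_finite)
    return center, relative


@dataclass(eq=False)
class AssociationIndex:
    """Genes x gene sets rho matrix with its centered-magnitude relative ranks."""

    gene_ids: tuple[str, ...]
    set_names: tuple[str, ...]
    rho: np.ndarray
    is_down: np.ndarray
    center: float
    relative_rank: np.ndarray
    n_finite: int
    _gene_pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_rho(cls, gene_ids, set_names, rho, is_down=None) -> "AssociationIndex":
        rho = np.asarray(rho, dtype=np.float64)
        gene_ids = tuple(gene_ids)
        set_names = tuple(set_names)
        if rho.shape != (len(gene_ids), len(set_names)):
            raise ValueError("rho shape inconsistent with gene/set ids")
        if is_down is None:
            is_down = np.zeros(len(set_names), dtype=bool)
        center, relative = center_and_rank(rho)
        return cls(gene_ids=gene_ids, set_names=set_names, rho=rho,
                   is_down=np.asarray(is_down, dtype=bool), center=center,
                   relative_rank=relative, n_finite=int(np.isfinite(rho).sum()))

    def gene_position(self, gene: str) -> int:
        try:
            return self._gene_pos[gene]
        except KeyError:
            raise KeyError(f"unknown gene: {gene!r}") from None


@dataclass(frozen=True)
class AssociationRecord:
    """One gene/gene-set association as reported to the user."""

    gene: str
    set_name: str
    rho: float
    reported_rho: float  # sign-flipped when the set is directional-down
    relative_rank: float
    flipped: bool
    loo_applied: bool = False


def _ranked_enrichment(enr: EnrichmentMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Centered, unit-norm midranks of each set's score profile.

    Returns (standardized rank matrix, mask of constant rows)."""
    ranks = stats.rankdata(enr.z, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks * ranks).sum(axis=1))
    constant = norms == 0.0
    norms[constant] = 1.0
    return ranks / norms[:, None], constant


def correlation_matrix(expr: ExpressionMatrix, enr: EnrichmentMatrix,
                       gene_block: int = DEFAULT_GENE_BLOCK) -> AssociationIndex:
    """Spearman rho between every gene's expression and every set's scores.

    Genes are processed in blocks of ``gene_block`` rows (the full matrix at
    genome scale can be large); the result is exactly independent of the
    block size. Constant expression or score profiles yield NaN (undefined)
    entries, which are excluded from the centered rank distribution.
    """
    if gene_block < 1:
        raise ValueError("gene_block must be >= 1")
    if expr.sample_ids != enr.sample_ids:
        raise ValueError("expression and enrichment matrices must share the "
                         "same sample order")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation")
    set_ranks, set_constant = _ranked_enrichment(enr)

    rho = np.empty((expr.n_genes, len(enr.set_names)), dtype=np.float64)
    for start in range(0, expr.n_genes, gene_block):
        block = expr.values[start:start + gene_block]
        ranks = stats.rankdata(block, axis=1)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((ranks * ranks).sum(axis=1))
        gene_constant = norms == 0.0
        norms[gene_constant] = 1.0
        ranks /= norms[:, None]
        # one matvec per gene: the summation path is then the same for every
        # gene_block, so results are bit-identical across block sizes
        for i in range(ranks.shape[0]):
            rho[start + i] = set_ranks @ ranks[i]
        rho[start:start + gene_block][gene_constant, :] = np.nan
    rho[:, set_constant] = np.nan
    return AssociationIndex.from_rho(expr.gene_ids, enr.set_names, rho,
                                     is_down=enr.is_down)


def _make_record(gene: str, set_name: str, rho: float, relative_rank: float,
                 is_down: bool, loo_applied: bool = False) -> AssociationRecord:
    return AssociationRecord(
        gene=gene, set_name=set_name, rho=float(rho),
        reported_rho=float(-rho if is_down else rho),
        relative_rank=float(relative_rank), flipped=bool(is_down),
        loo_applied=loo_applied)


def rank_gene_sets_for_gene(index: AssociationIndex, gene: str,
                            k: int | None = None,
                            exclude: list[str] | None = None) -> list[AssociationRecord]:
    """The gene sets most associated with ``gene``, strongest first.

    Records are sorted by relative rank ascending (ties broken by set name);
    "down" sets carry a sign-flipped ``reported_rho``. ``exclude`` omits named
    sets (e.g. uninterpretable cancer-module sets) from the ranking. ``k``
    larger than the number of sets returns them all.
    """
    g = index.gene_position(gene)
    excluded = set(exclude or ())
    records = [
        _make_record(gene, name, index.rho[g, j], index.relative_rank[g, j],
                     bool(index.is_down[j]))
        for j, name in enumerate(index.set_names)
        if name not in excluded and np.isfinite(index.rho[g, j])
    ]
    records.sort(key=lambda r: (r.relative_rank, r.set_name))
    return records if k is None else records[:k]


def rank_genes_for_gene_set(expr: ExpressionMatrix, prepared: PreparedGeneSet,
                            k: int | None = None, loo: bool = True,
                            ddof: int = 1,
                            index: AssociationIndex | None = None) -> list[AssociationRecord]:
    """The genes most associated with one gene set, by rho descending.

    For member genes the set's enrichment scores are recomputed with that
    gene removed (leave-one-out) so a gene cannot correlate with itself
    through the score; non-member genes are correlated against the full-set
    scores. Ties are broken by gene name. When an ``index`` covering this set
    is supplied, each record carries its global relative rank (NaN otherwise).
    """
    if prepared.m < 3:
        raise ValueError(f"set {prepared.name!r} needs m >= 3, got {prepared.m}")
    full = enrichment_matrix(expr, [prepared], ddof=ddof).z[0]
    members = set(prepared.effective_members)

    rel_col = None
    if index is not None and prepared.name in index.set_names:
        rel_col = index.relative_rank[:, index.set_names.index(prepared.name)]

    records: list[AssociationRecord] = []
    for i, gene in enumerate(expr.gene_ids):
        if loo and gene in members:
            scores = loo_enrichment_scores(expr, prepared, gene, ddof=ddof)
            applied = True
        else:
            scores = full
            applied = False
        rho = spearman_rho(expr.values[i], scores)
        rel = float("nan")
        if rel_col is not None and index is not None:
            rel = rel_col[index.gene_position(gene)] if gene in index._gene_pos else float("nan")
        records.append(_make_record(gene, prepared.name, rho, rel,
                                    prepared.is_down, loo_applied=applied))
    records = [r for r in records if np.isfinite(r.rho)]
    records.sort(key=lambda r: (-r.rho, r.gene))
    return records if k is None else records[:k]


def gene_set_frequency(index: AssociationIndex, top_n: int = 5) -> pd.Series:
    """How often each set appears among every gene's ``top_n`` associations.

    Only genes with at least ``top_n`` finite associations contribute, so the
    counts sum to (number of such genes) x ``top_n``. Returned sorted by count
    descending then set name; sets never appearing get count 0.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts: Counter[str] = Counter()
    names = np.array(index.set_names)
    for g in range(len(index.gene_ids)):
        rel = index.relative_rank[g]
        finite = np.isfinite(rel)
        if int(finite.sum()) < top_n:
            continue
        # sort by (relative_rank, name); lexsort keys are last-key-primary
        idx = np.flatnonzero(finite)
        order = idx[np.lexsort((names[idx], rel[idx]))][:top_n]
        counts.update(names[j] for j in order)
    series = pd.Series({name: counts.get(name, 0) for name in index.set_names},
                       name="count")
    order = np.lexsort((series.index.to_numpy(), -series.to_numpy()))
    return series.iloc[order]
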