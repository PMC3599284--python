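"""Turn raw log2 expression into control-standardized fold-changes and
prepare gene sets against the measured gene universe.

Fold-change here means a case sample's log2 expression minus the median log2
expression of the same gene across tissue-matched control samples. The
subtraction is done in log2 space (the inputs are assumed already
log-transformed, e.g. RMA summaries), so the output units are log2
fold-change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection, SampleGroupMap

log = logging.getLogger(__name__)

#: Gene-set size bounds applied by default: sets whose intersection with the
#: measured gene universe has fewer than 22 or more than 800 genes are removed
#: to limit biases from very small and very large sets.
DEFAULT_MIN_SET_SIZE = 22
DEFAULT_MAX_SET_SIZE = 800


@dataclass(frozen=True)
class PreparedGeneSet:
    """A gene set intersected with the measured gene universe.

    ``effective_members`` keeps the source member order; ``m`` is the
    effective set size used in the enrichment Z-score.
    """

    source: GeneSet
    effective_members: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.effective_members)

    @property
    def name(self) -> str:
        return self.source.name

    @property
    def is_down(self) -> bool:
        return self.source.is_down

    def member_positions(self, expr: ExpressionMatrix) -> np.ndarray:
        return np.fromiter((expr.gene_position(g) for g in self.effective_members),
                           dtype=np.intp, count=self.m)


def collapse_duplicate_genes(table: pd.DataFrame) -> ExpressionMatrix:
    """Collapse repeated gene rows to one row per gene by per-sample median."""
    n_dup = int(table.index.duplicated().sum())
    if n_dup == 0:
        return ExpressionMatrix.from_frame(table)
    log.warning("collapsing %d duplicate gene row(s) by per-sample median", n_dup)
    collapsed = table.groupby(level=0, sort=False).median()
    return ExpressionMatrix.from_frame(collapsed)


def standardize_to_matched_controls(cases: ExpressionMatrix,
                                    controls: ExpressionMatrix,
                                    groups: SampleGroupMap) -> ExpressionMatrix:
    """Standardize each case sample to the median of tissue-matched controls.

    ``output[g, t] = cases[g, t] - median over matched controls of controls[g, .]``

    Genes absent from either matrix are dropped with a warning. A case sample
    whose tissue group has no control samples is an error.
    """
    shared = [g for g in cases.gene_ids if g in set(controls.gene_ids)]
    dropped = (cases.n_genes - len(shared)) + (controls.n_genes - len(shared))
    if not shared:
        raise ValueError("case and control matrices share no genes")
    if dropped:
        log.warning("dropping %d gene(s) absent from one side of the case/control pair",
                    dropped)

    case_vals = cases.to_frame().loc[shared]
    ctrl_vals = controls.to_frame().loc[shared]
    ctrl_samples = set(controls.sample_ids)

    out = np.empty((len(shared), cases.n_samples), dtype=np.float64)
    medians: dict[str, np.ndarray] = {}
    for j, sid in enumerate(cases.sample_ids):
        group = groups.tissue_group(sid)
        if group not in medians:
            matched = [s for s in groups.controls_for_group(group) if s in ctrl_samples]
            if not matched:
                raise ValueError(f"tissue group {group!r} (case sample {sid!r}) "
                                 f"has no control samples")
            medians[group] = np.nanmedian(ctrl_vals[matched].to_numpy(), axis=1)
        out[:, j] = case_vals.iloc[:, j].to_numpy() - medians[group]
    return ExpressionMatrix(tuple(shared), cases.sample_ids, out)


def filter_gene_sets(collection: GeneSetCollection | list[GeneSet],
                     universe,
                     min_size: int = DEFAULT_MIN_SET_SIZE,
                     max_size: int = DEFAULT_MAX_SET_SIZE) -> list[PreparedGeneSet]:
    """Intersect sets with the measured universe and apply the size filter.

    A set is kept iff ``min_size <= m <= max_size`` where ``m`` is the size of
    the intersection (both bounds inclusive: removal is strict-below /
    strict-above). Order of kept sets follows the collection.
    """
    if min_size > max_size:
        raise ValueError(f"min_size ({min_size}) > max_size ({max_size})")
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("gene universe is empty")
    prepared: list[PreparedGeneSet] = []
    for s in collection:
        effective = tuple(g for g in s.members if g in universe_set)
        if min_size <= len(effective) <= max_size:
            prepared.append(PreparedGeneSet(source=s, effective_members=effective))
    return prepared


@dataclass
class VarianceFilterResult:
    """Result of :func:`filter_low_variance_genes`.

    ``zero_spread_genes`` lists retained genes whose spread statistic is
    exactly zero (constant rows); their Spearman correlations will be
    undefined downstream.
    """

    matrix: ExpressionMatrix
    removed_genes: tuple[str, ...]
    zero_spread_genes: tuple[str, ...]


_SPREAD_STATS = ("IQR", "MAD", "SD")


def _spread(values: np.ndarray, stat: str) -> np.ndarray:
    if stat == "IQR":
        q75, q25 = np.nanpercentile(values, [75, 25], axis=1)
        return q75 - q25
    if stat == "MAD":
        med = np.nanmedian(values, axis=1, keepdims=True)
        return np.nanmedian(np.abs(values - med), axis=1)
    if stat == "SD":
        return np.nanstd(values, axis=1, ddof=1)
    raise ValueError(f"spread_stat must be one of {_SPREAD_STATS}, got {stat!r}")


def filter_low_variance_genes(matrix: ExpressionMatrix,
                              min_spread: float = 0.0,
                              spread_stat: str = "IQR") -> VarianceFilterResult:
    """Remove genes whose spread statistic falls below ``min_spread``.

    With ``min_spread=0`` (the default) no gene is removed; exactly-constant
    genes are retained but flagged in ``zero_spread_genes`` since their
    correlations are undefined. The "well-measured gene" threshold is exposed,
    not imposed.
    """
    if min_spread < 0:
        raise ValueError("min_spread must be >= 0")
    spread = _spread(matrix.values, spread_stat)
    keep = spread >= min_spread if min_spread > 0 else np.ones(matrix.n_genes, bool)
    kept_genes = tuple(g for g, k in zip(matrix.gene_ids, keep) if k)
    removed = tuple(g for g, k in zip(matrix.gene_ids, keep) if not k)
    flagged = tuple(g for g, k, s in zip(matrix.gene_ids, keep, spread)
                    if k and s == 0.0)
    if removed:
        log.info("removed %d gene(s) with %s < %g", len(removed), spread_stat,
                 min_spread)
    return VarianceFilterResult(
        matrix=ExpressionMatrix(kept_genes, matrix.sample_ids, matrix.values[keep]),
        removed_genes=removed,
        zero_spread_genes=flagged,
    )


def require_complete(matrix: ExpressionMatrix,
                     on_missing: str = "error") -> ExpressionMatrix:
    """Enforce a complete matrix before enrichment.

    The per-sample mean and standard deviation in the enrichment score are
    whole-vector statistics, so missing values are disallowed downstream.
    ``on_missing='drop'`` removes genes with any missing value;
    ``'error'`` raises.
    """
    if not matrix.has_missing():
        return matrix
    if on_missing == "drop":
        keep = ~np.isnan(matrix.values).any(axis=1)
        log.warning("dropping %d gene(s) with missing values",
                    int((~keep).sum()))
        kept = tuple(g for g, k in zip(matrix.gene_ids, keep) if k)
        if not kept:
            raise ValueError("all genes have missing values")
        return ExpressionMatrix(kept, matrix.sample_ids, matrix.values[keep])
    if on_missing == "error":
        bad = [g for g, row in zip(matrix.gene_ids, np.isnan(matrix.values))
               if row.any()]
        raise ValueError(f"matrix has missing values in {len(bad)} gene(s), "
                         f"e.g. {bad[:3]}; impute or drop before enrichment")
    raise ValueError(f"on_missing must be 'error' or 'drop', got {on_missing!r}")
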