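"""Per-sample parametric gene-set enrichment Z-scores (Kim-Volsky / PGSEA style).

For one sample with fold-change vector x over all measured genes and a gene
set with m effective members,

    Z = (S_m - mu) * sqrt(m) / delta

where mu and delta are the mean and standard deviation of the *whole* vector
x (not of the set members — the most common implementation mistake) and S_m
is the mean fold-change of the set members. Z measures how far the set's
average expression sits from the sample's background, in units scaled by the
set size: large positive Z means the set is coordinately up in that sample.

delta defaults to the sample standard deviation (n-1 denominator), matching
the PGSEA lineage; the population denominator is available via ``ddof=0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix
from .preprocess import PreparedGeneSet


class DegenerateSampleError(ValueError):
    """A sample's fold-change vector is constant, so delta = 0 and Z is undefined."""


@dataclass(frozen=True)
class SampleEnrichmentContext:
    """All quantities entering one Z-score: mu, delta, S_m, m and Z itself."""

    mu: float
    delta: float
    s_m: float
    m: int
    z: float


@dataclass(eq=False)
class EnrichmentMatrix:
    """Gene sets x samples matrix of enrichment Z-scores."""

    set_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    z: np.ndarray
    is_down: np.ndarray | None = None  # per-set directionality, carried for ranking

    def __post_init__(self) -> None:
        self.set_names = tuple(self.set_names)
        self.sample_ids = tuple(self.sample_ids)
        self.z = np.asarray(self.z, dtype=np.float64)
        if len(set(self.set_names)) != len(self.set_names):
            raise ValueError("duplicate set names")
        if self.z.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("z shape inconsistent with set/sample ids")
        if not np.isfinite(self.z).all():
            raise ValueError("enrichment scores must be finite")
        if self.is_down is None:
            self.is_down = np.zeros(len(self.set_names), dtype=bool)
        else:
            self.is_down = np.asarray(self.is_down, dtype=bool)

    def row(self, set_name: str) -> np.ndarray:
        return self.z[self.set_names.index(set_name)]


def _column_stats(values: np.ndarray, ddof: int) -> tuple[np.ndarray, np.ndarray]:
    if np.isnan(values).any():
        raise ValueError("enrichment requires a complete matrix; impute or drop "
                         "missing values first (preprocess.require_complete)")
    mu = values.mean(axis=0)
    delta = values.std(axis=0, ddof=ddof)
    return mu, delta


def pgsea_z(sample_vector: np.ndarray, member_index: np.ndarray,
            ddof: int = 1) -> SampleEnrichmentContext:
    """Z-score of one gene set in one sample.

    ``sample_vector`` holds the fold-changes of *all* genes in the sample;
    ``member_index`` the positions of the set's effective members.
    """
    x = np.asarray(sample_vector, dtype=np.float64)
    idx = np.asarray(member_index, dtype=np.intp)
    if idx.size == 0:
        raise ValueError("member_index is empty")
    if np.isnan(x).any() or np.isinf(x).any():
        raise ValueError("sample vector must be finite")
    mu = float(x.mean())
    delta = float(x.std(ddof=ddof))
    if delta == 0.0:
        raise DegenerateSampleError("sample vector is constant (delta = 0)")
    m = int(idx.size)
    s_m = float(x[idx].mean())
    z = (s_m - mu) * np.sqrt(m) / delta
    return SampleEnrichmentContext(mu=mu, delta=delta, s_m=s_m, m=m, z=float(z))


def enrichment_matrix(expr: ExpressionMatrix, prepared: list[PreparedGeneSet],
                      ddof: int = 1) -> EnrichmentMatrix:
    """Z-scores for every prepared set in every sample.

    ``z[k, t]`` is bit-for-bit equal to ``pgsea_z(column t, members of set k).z``;
    the computation is merely vectorized per sample.
    """
    if not prepared:
        raise ValueError("no prepared gene sets")
    names = [p.name for p in prepared]
    mu, delta = _column_stats(expr.values, ddof)
    degenerate = np.flatnonzero(delta == 0.0)
    if degenerate.size:
        raise DegenerateSampleError(
            f"constant fold-change vector in sample(s) "
            f"{[expr.sample_ids[i] for i in degenerate[:5]]}")
    z = np.empty((len(prepared), expr.n_samples), dtype=np.float64)
    for k, p in enumerate(prepared):
        idx = p.member_positions(expr)
        s_m = expr.values[idx].mean(axis=0)
        z[k] = (s_m - mu) * np.sqrt(p.m) / delta
    return EnrichmentMatrix(tuple(names), expr.sample_ids, z,
                            is_down=np.array([p.is_down for p in prepared]))


def loo_enrichment_scores(expr: ExpressionMatrix, prepared: PreparedGeneSet,
                          gene: str, ddof: int = 1) -> np.ndarray:
    """Per-sample Z-scores with ``gene`` removed from the set (leave-one-out).

    Removing the gene prevents it from correlating with itself through the
    score. mu and delta are whole-sample statistics and are unchanged; only
    S_m and m shrink. If ``gene`` is not an effective member the full-set
    scores are returned unchanged.
    """
    mu, delta = _column_stats(expr.values, ddof)
    if (delta == 0.0).any():
        raise DegenerateSampleError("constant fold-change vector in some sample")
    idx = prepared.member_positions(expr)
    if gene in prepared.effective_members:
        if prepared.m - 1 < 2:
            raise ValueError(
                f"set {prepared.name!r} too small after removing {gene!r} "
                f"(m - 1 = {prepared.m - 1} < 2)")
        idx = idx[idx != expr.gene_position(gene)]
    m = idx.size
    s_m = expr.values[idx].mean(axis=0)
    return (s_m - mu) * np.sqrt(m) / delta
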