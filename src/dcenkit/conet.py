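"""Per-individual signed co-expression networks and the consistency prefilter.

For each individual i, the Pearson correlation r_ghi between every gene pair
(g, h) is computed over that individual's m time-ordered values.  Under the
null of no correlation the statistic

    t = r * sqrt((m - 2) / (1 - r^2))

follows a Student t distribution with m - 2 degrees of freedom, giving a
two-sided p-value p_ghi.  The signed edge weight is

    w_ghi = sgn(r_ghi) * (1 - p_ghi)

(signed complementary significance), which lies in [-1, 1], is monotone in
|r| for fixed m, and makes the prefilter p < 0.05 equivalent to |w| > 0.95.
An alternative weight strategy (the raw correlation) can be plugged in.

The consistency mask a_gh retains a gene pair when it is significantly
correlated, with a consistent sign, in enough individuals of at least one
group: the per-group count threshold is

    T_G = max(ceil(frac * n_G), min(min_count, n_G), 1)

with defaults frac = 0.25 and min_count = 2 ("at least 25% of the
individuals, with a minimum of two if available").
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionDataset

__all__ = [
    "IndividualCorrelationNetwork",
    "ConsistencyMask",
    "correlation_pvalue",
    "significance_weight",
    "correlation_weight",
    "build_individual_network",
    "build_all_networks",
    "consistency_mask",
    "group_threshold",
]


def correlation_pvalue(r, m: int):
    """Two-sided p-value of a Pearson correlation from m observations.

    Accepts a scalar or array of correlations.  |r| = 1 maps to p = 0 (limit
    convention).  Requires m >= 3 for the m - 2 degrees of freedom.
    """
    if m < 3:
        raise ValueError(f"need at least 3 time points, got m={m}")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    df = m - 2
    with np.errstate(divide="ignore"):
        t = r_arr * np.sqrt(df / (1.0 - r_arr**2))
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return float(p) if np.isscalar(r) else p


def significance_weight(r, p):
    """Default edge weight: sgn(r) * (1 - p)."""
    return np.sign(r) * (1.0 - np.asarray(p, dtype=float))


def correlation_weight(r, p):
    """Alternative weight strategy: the raw correlation."""
    return np.asarray(r, dtype=float).copy()


@dataclasses.dataclass
class IndividualCorrelationNetwork:
    """Gene-pair correlations, p-values and signed weights for one individual."""

    individual_id: str
    genes: list[str]
    r: np.ndarray  # symmetric, diagonal 1
    p: np.ndarray  # symmetric, diagonal 0
    w: np.ndarray  # symmetric, diagonal 0
    m: int         # number of time points

    def __post_init__(self) -> None:
        n = len(self.genes)
        for name in ("r", "p", "w"):
            mat = getattr(self, name)
            if mat.shape != (n, n):
                raise ValueError(f"{name} matrix shape {mat.shape} != ({n}, {n})")
        if self.m < 3:
            raise ValueError(f"m must be >= 3, got {self.m}")


def build_individual_network(
    ds: ExpressionDataset,
    individual_id: str,
    weight_fn: Callable = significance_weight,
) -> IndividualCorrelationNetwork:
    """Pearson correlation network over one individual's time series.

    Genes that are constant within the individual are treated as uncorrelated
    with everything: r = 0, p = 1, w = 0 for every pair involving them.
    """
    values = ds.individual_matrix(individual_id)
    m = values.shape[1]
    if m < 3:
        raise ValueError(
            f"individual {individual_id!r} has m={m} < 3 time points"
        )
    sd = values.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.asarray(r, dtype=float)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)

    p = correlation_pvalue(r, m)
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)

    w = weight_fn(r, p)
    w[constant, :] = 0.0
    w[:, constant] = 0.0
    np.fill_diagonal(w, 0.0)
    return IndividualCorrelationNetwork(
        individual_id=individual_id, genes=list(ds.genes), r=r, p=p, w=w, m=m
    )


def build_all_networks(
    ds: ExpressionDataset, weight_fn: Callable = significance_weight
) -> list[IndividualCorrelationNetwork]:
    return [
        build_individual_network(ds, ind, weight_fn=weight_fn)
        for ind in ds.individuals
    ]


@dataclasses.dataclass
class ConsistencyMask:
    """Binary symmetric gene-pair retention mask a_gh with its thresholds."""

    genes: list[str]
    a: np.ndarray  # 0/1, symmetric, zero diagonal
    p_cut: float
    frac: float
    min_count: int

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.a.shape != (n, n):
            raise ValueError("mask shape does not match gene list")

    @property
    def n_retained_pairs(self) -> int:
        return int(self.a.sum() // 2)


def group_threshold(n_group: int, frac: float, min_count: int) -> int:
    """Per-group count threshold T_G = max(ceil(frac*n), min(min_count, n), 1)."""
    return max(math.ceil(frac * n_group), min(min_count, n_group), 1)


def consistency_mask(
    nets: Sequence[IndividualCorrelationNetwork],
    groups: Mapping[str, str],
    p_cut: float = 0.05,
    frac: float = 0.25,
    min_count: int = 2,
) -> ConsistencyMask:
    """Retain gene pairs consistently correlated within at least one group.

    A pair passes for group G when at least T_G of its individuals show a
    significant (p < p_cut) correlation of the same sign; positive and
    negative counts are assessed separately, so evidence of mixed sign does
    not accumulate.
    """
    if not nets:
        raise ValueError("no individual networks given")
    genes = nets[0].genes
    for net in nets:
        if net.genes != genes:
            raise ValueError("networks have mismatched gene universes")
        if net.individual_id not in groups:
            raise ValueError(
                f"individual {net.individual_id!r} missing from group map"
            )
    labels = sorted(set(groups[n.individual_id] for n in nets))
    n_genes = len(genes)
    a = np.zeros((n_genes, n_genes), dtype=bool)
    for label in labels:
        members = [n for n in nets if groups[n.individual_id] == label]
        if not members:
            raise ValueError(f"group {label!r} has no individuals")
        threshold = group_threshold(len(members), frac, min_count)
        k_pos = np.zeros((n_genes, n_genes), dtype=int)
        k_neg = np.zeros((n_genes, n_genes), dtype=int)
        for net in members:
            sig = net.p < p_cut
            k_pos += sig & (net.r > 0)
            k_neg += sig & (net.r < 0)
        a |= (k_pos >= threshold) | (k_neg >= threshold)
    np.fill_diagonal(a, False)
    return ConsistencyMask(
        genes=list(genes),
        a=a.astype(np.int8),
        p_cut=p_cut,
        frac=frac,
        min_count=min_count,
    )
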