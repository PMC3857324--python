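"""The DCeN score: differential co-expression of a gene's neighborhood.

Given per-individual weight matrices w_ghi, the weights are averaged within
each group,

    wbar_X(g,h) = (1/n_X) * sum_{i in X} w_ghi     (and likewise for Y),

and each gene g is scored over its retained neighborhood {h : a_gh = 1}:

    d_g = sum_h a_gh |wbar_X(g,h) - wbar_Y(g,h)|
          -----------------------------------------------
          sum_h a_gh (|wbar_X(g,h)| + |wbar_Y(g,h)|)

with d_g = 0 when the denominator is zero (no retained, non-trivial
neighborhood).  The numerator is the changed neighborhood, the denominator
the total neighborhood; 0 <= d_g <= 1, d_g = 0 when the neighborhoods are
equal, and d_g = 1 exactly when for every retained neighbor the weaker
group-averaged weight is zero or of opposite sign to the stronger one.

Significance is assessed by permuting the group labels of whole individuals
(keeping each time series intact and the group sizes fixed), recomputing the
mask, averages and scores each time, and pooling the null scores of all genes
across permutations.  The p-value uses an add-one correction:

    p(g) = (1 + #{null >= d_g}) / (1 + n_perm * n_genes).
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np

from .conet import (
    ConsistencyMask,
    IndividualCorrelationNetwork,
    consistency_mask,
    group_threshold,
)

__all__ = [
    "GroupAveragedWeights",
    "average_weights",
    "dcen_score",
    "pooled_permutation_pvalues",
    "permutation_null_scores",
    "switching_neighborhood",
]


@dataclasses.dataclass
class GroupAveragedWeights:
    """Group-wise arithmetic means of the individual weight matrices.

    ``x_label`` is the lexicographically smaller group label; the score is
    symmetric in the two groups, so this affects only labeling.
    """

    genes: list[str]
    x_label: str
    y_label: str
    wbar_x: np.ndarray
    wbar_y: np.ndarray
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.wbar_x.shape != (n, n) or self.wbar_y.shape != (n, n):
            raise ValueError("averaged weight matrices do not match gene list")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("each group needs at least one individual")


def average_weights(
    nets: Sequence[IndividualCorrelationNetwork],
    groups: Mapping[str, str],
) -> GroupAveragedWeights:
    """Average the individual weight matrices within each of the two groups."""
    if not nets:
        raise ValueError("no individual networks given")
    genes = nets[0].genes
    labels = sorted({groups[n.individual_id] for n in nets})
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    stacks: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    for net in nets:
        if net.genes != genes:
            raise ValueError("networks have mismatched gene universes")
        stacks[groups[net.individual_id]].append(net.w)
    for lab in labels:
        if not stacks[lab]:
            raise ValueError(f"group {lab!r} has no individuals")
    x_label, y_label = labels
    return GroupAveragedWeights(
        genes=list(genes),
        x_label=x_label,
        y_label=y_label,
        wbar_x=np.mean(stacks[x_label], axis=0),
        wbar_y=np.mean(stacks[y_label], axis=0),
        n_x=len(stacks[x_label]),
        n_y=len(stacks[y_label]),
    )


def dcen_score(avw: GroupAveragedWeights, mask: ConsistencyMask) -> np.ndarray:
    """Per-gene DCeN scores d_g over the retained neighborhoods."""
    if mask.genes != avw.genes:
        raise ValueError("mask and averaged weights have mismatched genes")
    a = mask.a.astype(bool)
    diff = np.abs(avw.wbar_x - avw.wbar_y)
    total = np.abs(avw.wbar_x) + np.abs(avw.wbar_y)
    num = np.where(a, diff, 0.0).sum(axis=1)
    den = np.where(a, total, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return d


def _scores_for_assignment(
    w_stack: np.ndarray,
    sig_pos: np.ndarray,
    sig_neg: np.ndarray,
    is_x: np.ndarray,
    frac: float,
    min_count: int,
) -> np.ndarray:
    """Mask + averages + scores for one assignment of individuals to groups.

    ``w_stack``, ``sig_pos``, ``sig_neg`` have shape (n_individuals, G, G);
    ``is_x`` is a boolean vector over individuals.  Used by the permutation
    machinery so the per-individual networks are computed only once.
    """
    n_x = int(is_x.sum())
    n_y = int((~is_x).sum())
    t_x = group_threshold(n_x, frac, min_count)
    t_y = group_threshold(n_y, frac, min_count)
    kx_pos = sig_pos[is_x].sum(axis=0)
    kx_neg = sig_neg[is_x].sum(axis=0)
    ky_pos = sig_pos[~is_x].sum(axis=0)
    ky_neg = sig_neg[~is_x].sum(axis=0)
    a = (kx_pos >= t_x) | (kx_neg >= t_x) | (ky_pos >= t_y) | (ky_neg >= t_y)
    np.fill_diagonal(a, False)
    wbar_x = w_stack[is_x].mean(axis=0)
    wbar_y = w_stack[~is_x].mean(axis=0)
    diff = np.abs(wbar_x - wbar_y)
    total = np.abs(wbar_x) + np.abs(wbar_y)
    num = np.where(a, diff, 0.0).sum(axis=1)
    den = np.where(a, total, 0.0).sum(axis=1)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def permutation_null_scores(
    nets: Sequence[IndividualCorrelationNetwork],
    groups: Mapping[str, str],
    n_perm: int,
    seed: int | np.random.Generator,
    p_cut: float = 0.05,
    frac: float = 0.25,
    min_count: int = 2,
) -> np.ndarray:
    """Null DCeN scores from n_perm random group-label permutations.

    The permutation unit is the whole individual: each individual keeps its
    time series and only its group label is reassigned, preserving the
    original group sizes.  Returns an (n_perm, n_genes) array.
    """
    labels = sorted({groups[n.individual_id] for n in nets})
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    x_label = labels[0]
    n_x = sum(1 for n in nets if groups[n.individual_id] == x_label)
    n_y = len(nets) - n_x
    if n_x < 2 or n_y < 2:
        raise ValueError(
            "permutation test needs at least 2 individuals per group"
        )
    w_stack = np.stack([n.w for n in nets])
    sig = np.stack([n.p < p_cut for n in nets])
    r_pos = np.stack([n.r > 0 for n in nets])
    sig_pos = sig & r_pos
    sig_neg = sig & ~r_pos
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_ind = len(nets)
    null = np.empty((n_perm, len(nets[0].genes)))
    for b in range(n_perm):
        perm = rng.permutation(n_ind)
        is_x = np.zeros(n_ind, dtype=bool)
        is_x[perm[:n_x]] = True
        null[b] = _scores_for_assignment(
            w_stack, sig_pos, sig_neg, is_x, frac, min_count
        )
    return null


def pooled_permutation_pvalues(
    observed: np.ndarray, null_scores: np.ndarray
) -> np.ndarray:
    """Add-one empirical p-values against the pooled null.

    The null scores of all genes over all permutations form one pooled
    empirical null; p(g) = (1 + #{null >= d_g}) / (1 + null size).
    """
    pooled = np.sort(np.ravel(null_scores))
    n_null = pooled.size
    # count of null values >= observed, via left insertion point
    n_ge = n_null - np.searchsorted(pooled, observed, side="left")
    return (1.0 + n_ge) / (1.0 + n_null)


def switching_neighborhood(
    avw: GroupAveragedWeights,
    focal_gene: str,
    diff_fraction: float = 0.005,
    edge_cut: float = 0.95,
) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, float]]]:
    """Condition-specific strong-edge networks around a focal gene.

    Selects the ceil(diff_fraction * n_genes) genes with the largest absolute
    difference in group-averaged co-expression with the focal gene (ties
    broken lexicographically), then returns for each condition the edges
    among the focal + selected genes whose |group-averaged weight| exceeds
    ``edge_cut``.
    """
    if not 0 < diff_fraction <= 1:
        raise ValueError(f"diff_fraction must be in (0, 1], got {diff_fraction}")
    genes = avw.genes
    try:
        f = genes.index(focal_gene)
    except ValueError:
        raise KeyError(f"unknown focal gene {focal_gene!r}") from None
    n_genes = len(genes)
    diff = np.abs(avw.wbar_x[f] - avw.wbar_y[f])
    candidates = [i for i in range(n_genes) if i != f]
    candidates.sort(key=lambda i: (-diff[i], genes[i]))
    n_sel = min(math.ceil(diff_fraction * n_genes), len(candidates))
    selected = candidates[:n_sel]
    sub = sorted([f, *selected], key=lambda i: genes[i])

    def edges_for(wbar: np.ndarray) -> list[tuple[str, str, float]]:
        out = []
        for i, j in itertools.combinations(sub, 2):
            if abs(wbar[i, j]) > edge_cut:
                out.append((genes[i], genes[j], float(wbar[i, j])))
        return out

    return edges_for(avw.wbar_x), edges_for(avw.wbar_y)
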