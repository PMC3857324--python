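"""Evaluation harnesses: top-list reproducibility and gene-label enrichment.

Reproducibility of a ranking method is measured by drawing, repeatedly, two
disjoint subsamples of individuals per group, ranking each sub-cohort, and
recording the relative overlap of the two top-k lists.  Biological relevance
of a given ranking is assessed by comparing the mean of an external per-gene
property over the top-k list to its permutation null (property values
shuffled over gene labels).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import ConnectivityModel
from .io import ExpressionDataset, RankedGeneList
from .model import DCeN

__all__ = [
    "ReproducibilityResult",
    "EnrichmentResult",
    "top_overlap",
    "subsample_reproducibility",
    "enrichment_permutation",
    "make_ranker",
    "RANKERS",
]


def top_overlap(list_a: RankedGeneList, list_b: RankedGeneList, k: int) -> float:
    """Relative overlap |top-k(a) ∩ top-k(b)| / k of two rankings."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    universe_a, universe_b = set(list_a.genes), set(list_b.genes)
    if universe_a != universe_b:
        raise ValueError("ranked lists cover different gene universes")
    if k > len(universe_a):
        raise ValueError(f"k={k} exceeds the {len(universe_a)}-gene universe")
    return len(set(list_a.top(k)) & set(list_b.top(k))) / k


# -- ranking-method registry -------------------------------------------------


def _rank_dcen(ds: ExpressionDataset, rng: np.random.Generator, **kw):
    return DCeN(ds, **kw).fit().ranked_list()


def _rank_baseline(method):
    def ranker(ds: ExpressionDataset, rng: np.random.Generator, **kw):
        return ConnectivityModel(ds, method=method, **kw).fit().ranked_list()

    return ranker


def _rank_random(ds: ExpressionDataset, rng: np.random.Generator, **kw):
    scores = dict(zip(ds.genes, rng.random(ds.n_genes)))
    return RankedGeneList.from_scores(scores)


RANKERS: dict[str, Callable] = {
    "dcen": _rank_dcen,
    "avg": _rank_baseline("average"),
    "concat": _rank_baseline("concat"),
    "indcorr": _rank_baseline("indcorr"),
    "random": _rank_random,
}


def make_ranker(method, **kwargs) -> Callable:
    """Resolve a method name (or pass through a callable) to a ranker.

    A ranker maps ``(dataset, rng)`` to a :class:`RankedGeneList`.
    """
    if callable(method):
        return method
    if method not in RANKERS:
        raise ValueError(
            f"unknown ranking method {method!r}; choose from {sorted(RANKERS)}"
        )
    base = RANKERS[method]
    if kwargs:
        return lambda ds, rng: base(ds, rng, **kwargs)
    return base


@dataclasses.dataclass
class ReproducibilityResult:
    """Mean relative top-k overlap over pairs of disjoint sub-cohorts."""

    method: str
    n_per_group: int
    top_sizes: list[int]
    mean_relative_overlap: dict[int, float]
    se: dict[int, float]
    n_pairs: int
    overlaps: pd.DataFrame = dataclasses.field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "top_size": self.top_sizes,
                "mean_relative_overlap": [
                    self.mean_relative_overlap[k] for k in self.top_sizes
                ],
                "se": [self.se[k] for k in self.top_sizes],
                "n_pairs": self.n_pairs,
                "method": self.method,
                "n_per_group": self.n_per_group,
            }
        )


def subsample_reproducibility(
    ds: ExpressionDataset,
    method,
    n_per_group: int,
    n_pairs: int = 100,
    top_sizes: Sequence[int] = (200,),
    seed: int | None = None,
    **method_kwargs,
) -> ReproducibilityResult:
    """Top-list overlap between rankings of disjoint sub-cohorts.

    Each repetition draws 2*n_per_group individuals per group without
    replacement and splits them into two disjoint sub-cohorts of n_per_group
    per group; both are ranked with ``method`` and the relative top-k overlap
    recorded for each k in ``top_sizes``.  Reported are the mean and the
    empirical standard error over ``n_pairs`` repetitions.
    """
    if seed is None:
        raise ValueError("a seed is required (subsampling is stochastic)")
    ranker = make_ranker(method, **method_kwargs)
    rng = np.random.default_rng(seed)
    group_of = ds.group_of
    by_group: dict[str, list[str]] = {}
    for ind in ds.individuals:
        by_group.setdefault(group_of[ind], []).append(ind)
    for label, members in by_group.items():
        if len(members) < 2 * n_per_group:
            raise ValueError(
                f"group {label!r} has {len(members)} individuals; "
                f"need at least {2 * n_per_group} for disjoint "
                f"sub-cohorts of {n_per_group}"
            )
    top_sizes = [int(k) for k in top_sizes]
    records = np.empty((n_pairs, len(top_sizes)))
    for rep in range(n_pairs):
        first: list[str] = []
        second: list[str] = []
        for members in by_group.values():
            drawn = rng.choice(members, size=2 * n_per_group, replace=False)
            first.extend(drawn[:n_per_group])
            second.extend(drawn[n_per_group:])
        rank_a = ranker(ds.subset_individuals(first), rng)
        rank_b = ranker(ds.subset_individuals(second), rng)
        for j, k in enumerate(top_sizes):
            records[rep, j] = top_overlap(rank_a, rank_b, k)
    mean = records.mean(axis=0)
    se = records.std(axis=0, ddof=1) / np.sqrt(n_pairs) if n_pairs > 1 else (
        np.zeros(len(top_sizes))
    )
    return ReproducibilityResult(
        method=method if isinstance(method, str) else getattr(
            method, "__name__", "custom"
        ),
        n_per_group=n_per_group,
        top_sizes=top_sizes,
        mean_relative_overlap=dict(zip(top_sizes, mean)),
        se=dict(zip(top_sizes, se)),
        n_pairs=n_pairs,
        overlaps=pd.DataFrame(records, columns=top_sizes),
    )


@dataclasses.dataclass
class EnrichmentResult:
    """Observed mean property over top-k lists vs its gene-label null."""

    top_sizes: list[int]
    observed_statistic: dict[int, float]
    p_value: dict[int, float]
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "top_size": self.top_sizes,
                "observed": [self.observed_statistic[k] for k in self.top_sizes],
                "p_value": [self.p_value[k] for k in self.top_sizes],
                "n_perm": self.n_perm,
            }
        )


def enrichment_permutation(
    ranking: RankedGeneList,
    prop: Mapping[str, float],
    top_sizes: Sequence[int],
    n_perm: int = 10000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Permutation enrichment of an external per-gene property in the top list.

    The observed statistic at size k is the mean property over the top-k
    genes; the null redistributes the property values over the gene labels
    ``n_perm`` times.  One-sided (greater), with add-one correction:
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if seed is None:
        raise ValueError("a seed is required (label permutation is stochastic)")
    genes = ranking.genes
    missing = [g for g in genes if g not in prop]
    if missing:
        raise ValueError(
            f"property missing for ranked genes, e.g. {missing[:3]}; "
            "restrict the ranking to annotated genes first"
        )
    values = np.asarray([float(prop[g]) for g in genes])
    top_sizes = [int(k) for k in top_sizes]
    for k in top_sizes:
        if not 0 < k <= len(genes):
            raise ValueError(f"top size {k} outside 1..{len(genes)}")
    observed = {k: float(values[:k].mean()) for k in top_sizes}
    if np.allclose(values, values[0]):
        warnings.warn(
            "property is constant across genes; enrichment is undefined "
            "and all p-values are 1",
            stacklevel=2,
        )
        return EnrichmentResult(
            top_sizes=top_sizes,
            observed_statistic=observed,
            p_value={k: 1.0 for k in top_sizes},
            n_perm=n_perm,
        )
    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in top_sizes}
    for _ in range(n_perm):
        shuffled = rng.permutation(values)
        csum = np.cumsum(shuffled)
        for k in top_sizes:
            if csum[k - 1] / k >= observed[k] - 1e-12:
                counts[k] += 1
    p_value = {k: (1 + counts[k]) / (1 + n_perm) for k in top_sizes}
    return EnrichmentResult(
        top_sizes=top_sizes,
        observed_statistic=observed,
        p_value=p_value,
        n_perm=n_perm,
    )
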