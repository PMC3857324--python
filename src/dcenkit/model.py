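"""Model/Results interface over the DCeN pipeline.

`DCeN` is constructed from an :class:`~dcenkit.io.ExpressionDataset` (two
groups of individuals, each with a short expression time series) and exposes
the full procedure behind one `fit()` call:

>>> model = DCeN(dataset, p_cut=0.05, frac=0.25, min_count=2)
>>> res = model.fit(n_perm=100, seed=13)
>>> res.scores          # pandas Series of d_g per gene
>>> res.ranked_list()   # RankedGeneList with permutation p-values
>>> print(res.summary())

The heavy intermediate objects (per-individual networks, the consistency
mask, the group-averaged weights) are cached on the model and reachable from
the results, so the switching-neighborhood view and network exports reuse
them.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd

from . import conet, dcen
from .io import ExpressionDataset, RankedGeneList

__all__ = ["DCeN", "DCeNResults"]


class DCeN:
    """Dynamically Co-expressed Neighborhoods model for a two-group cohort.

    Parameters
    ----------
    dataset
        Expression dataset with exactly two groups and >= 3 time points per
        individual.
    p_cut, frac, min_count
        Consistency-prefilter parameters: a gene pair is retained when its
        correlation is significant (p < p_cut) with a consistent sign in at
        least max(ceil(frac * n_G), min(min_count, n_G), 1) individuals of at
        least one group.
    weight_fn
        Edge-weight strategy mapping (r, p) matrices to weights; defaults to
        sgn(r) * (1 - p).
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        p_cut: float = 0.05,
        frac: float = 0.25,
        min_count: int = 2,
        weight_fn: Callable = conet.significance_weight,
    ) -> None:
        if len(dataset.groups) != 2:
            raise ValueError(
                f"DCeN compares exactly two groups, dataset has {dataset.groups}"
            )
        if not 0 < p_cut <= 1:
            raise ValueError(f"p_cut must be in (0, 1], got {p_cut}")
        self.dataset = dataset
        self.p_cut = p_cut
        self.frac = frac
        self.min_count = min_count
        self.weight_fn = weight_fn
        self._networks: list[conet.IndividualCorrelationNetwork] | None = None

    @classmethod
    def from_files(cls, matrix_path, design_path, **kwargs) -> "DCeN":
        from .io import read_expression

        return cls(read_expression(matrix_path, design_path), **kwargs)

    @property
    def networks(self) -> list[conet.IndividualCorrelationNetwork]:
        """Per-individual correlation networks (computed once, cached)."""
        if self._networks is None:
            self._networks = conet.build_all_networks(
                self.dataset, weight_fn=self.weight_fn
            )
        return self._networks

    def fit(
        self, n_perm: int | None = None, seed: int | None = None
    ) -> "DCeNResults":
        """Run the pipeline; with ``n_perm`` also permutation p-values.

        ``seed`` is required whenever ``n_perm`` is given: the permutation
        null is the only stochastic step and must be reproducible.
        """
        groups = self.dataset.group_of
        nets = self.networks
        mask = conet.consistency_mask(
            nets, groups, p_cut=self.p_cut, frac=self.frac,
            min_count=self.min_count,
        )
        avw = dcen.average_weights(nets, groups)
        scores = dcen.dcen_score(avw, mask)
        pvalues = None
        null_scores = None
        if n_perm is not None:
            if n_perm < 1:
                raise ValueError("n_perm must be >= 1")
            if seed is None:
                raise ValueError("a seed is required for permutation p-values")
            null_scores = dcen.permutation_null_scores(
                nets, groups, n_perm=n_perm, seed=seed,
                p_cut=self.p_cut, frac=self.frac, min_count=self.min_count,
            )
            pvalues = dcen.pooled_permutation_pvalues(scores, null_scores)
        return DCeNResults(
            model=self,
            mask=mask,
            averaged=avw,
            scores=pd.Series(scores, index=self.dataset.genes, name="d"),
            pvalues=(
                None
                if pvalues is None
                else pd.Series(pvalues, index=self.dataset.genes, name="p")
            ),
            n_perm=n_perm,
            seed=seed,
            null_scores=null_scores,
        )


@dataclasses.dataclass
class DCeNResults:
    """Fitted DCeN scores with optional permutation significance."""

    model: DCeN
    mask: conet.ConsistencyMask
    averaged: dcen.GroupAveragedWeights
    scores: pd.Series
    pvalues: pd.Series | None
    n_perm: int | None
    seed: int | None
    null_scores: np.ndarray | None = dataclasses.field(default=None, repr=False)

    def ranked_list(self) -> RankedGeneList:
        return RankedGeneList.from_scores(
            self.scores.to_dict(),
            None if self.pvalues is None else self.pvalues.to_dict(),
        )

    def switching_neighborhood(
        self,
        focal_gene: str,
        diff_fraction: float = 0.005,
        edge_cut: float = 0.95,
    ):
        """Condition-specific strong-edge networks around ``focal_gene``."""
        return dcen.switching_neighborhood(
            self.averaged, focal_gene,
            diff_fraction=diff_fraction, edge_cut=edge_cut,
        )

    def summary(self, top: int = 10) -> str:
        m = self.model
        avw = self.averaged
        lines = [
            "Dynamically Co-expressed Neighborhoods (DCeN)",
            "=" * 45,
            f"genes: {len(self.scores)}    "
            f"groups: {avw.x_label} (n={avw.n_x}) vs {avw.y_label} (n={avw.n_y})",
            f"prefilter: p<{m.p_cut:g}, frac={m.frac:g}, min_count={m.min_count}"
            f"    retained pairs: {self.mask.n_retained_pairs}",
        ]
        if self.n_perm is not None:
            lines.append(
                f"permutations: {self.n_perm} (seed={self.seed}), "
                "pooled empirical null"
            )
        lines.append("-" * 45)
        ranked = self.ranked_list().table.head(top)
        header = f"{'rank':>4}  {'gene':<12}  {'d':>8}"
        if self.pvalues is not None:
            header += f"  {'p':>10}"
        lines.append(header)
        for row in ranked.itertuples(index=False):
            line = f"{row.rank:>4}  {row.gene_id:<12}  {row.score:>8.4f}"
            if self.pvalues is not None:
                line += f"  {row.p_value:>10.4g}"
            lines.append(line)
        return "\n".join(lines)
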