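"""Baseline differential co-expression strategies.

Analogs of the three classical ways of collapsing a grouped time-series
cohort into one association matrix per group before differencing:

``average``
    Average the individuals' time series point-wise within each group, then
    correlate the group-mean profiles.  Requires a common time grid; loses
    correlation when individuals traverse the process at different speeds.
``concat``
    Concatenate the individuals' time series end-to-end within each group
    (optionally after per-individual gene-wise centering) and correlate the
    concatenated vectors.
``indcorr``
    Correlate within each individual, then average the raw correlations
    within each group.

Each strategy yields per-group gene-pair association matrices s_X, s_Y; a
WGCNA-style soft-thresholded connectivity difference

    score(g) = sum_{h != g} | |s_X(g,h)|^beta - |s_Y(g,h)|^beta |

turns them into a per-gene ranking.  These are deliberately labelled analogs
of the published average/concatenation/individual-correlation strategies,
not clones of any particular package.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .conet import IndividualCorrelationNetwork, build_all_networks
from .io import ExpressionDataset, RankedGeneList
from .preprocess import center_individuals

__all__ = [
    "GroupCorrelationNetwork",
    "average_profile_network",
    "concat_network",
    "indcorr_network",
    "connectivity_rank",
    "ConnectivityModel",
    "ConnectivityResults",
]

_METHODS = ("average", "concat", "indcorr")


@dataclasses.dataclass
class GroupCorrelationNetwork:
    """Per-group gene-pair association matrices from one baseline strategy."""

    method: str
    genes: list[str]
    x_label: str
    y_label: str
    s_x: np.ndarray
    s_y: np.ndarray
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        n = len(self.genes)
        if self.s_x.shape != (n, n) or self.s_y.shape != (n, n):
            raise ValueError("association matrices do not match gene list")


def _safe_corrcoef(values: np.ndarray) -> np.ndarray:
    """Pearson matrix with constant rows mapped to zero association."""
    constant = values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.corrcoef(values)
    s = np.asarray(s, dtype=float)
    s[constant, :] = 0.0
    s[:, constant] = 0.0
    s = np.clip(s, -1.0, 1.0)
    np.fill_diagonal(s, 0.0)
    return s


def _two_labels(ds: ExpressionDataset) -> tuple[str, str]:
    labels = ds.groups
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    return labels[0], labels[1]


def average_profile_network(ds: ExpressionDataset) -> GroupCorrelationNetwork:
    """Correlation between per-group mean time profiles.

    Every individual in a group must share the same time grid so the
    point-wise mean profile is defined.
    """
    x_label, y_label = _two_labels(ds)
    matrices: dict[str, np.ndarray] = {}
    group_of = ds.group_of
    for label in (x_label, y_label):
        members = [i for i in ds.individuals if group_of[i] == label]
        grids = [tuple(ds.individual_times(i)) for i in members]
        if len(set(grids)) > 1:
            raise ValueError(
                f"individuals in group {label!r} have different time grids; "
                "the average-profile strategy requires a common grid "
                "(resample upstream)"
            )
        mean_profile = np.mean(
            [ds.individual_matrix(i) for i in members], axis=0
        )
        matrices[label] = _safe_corrcoef(mean_profile)
    return GroupCorrelationNetwork(
        method="average", genes=list(ds.genes),
        x_label=x_label, y_label=y_label,
        s_x=matrices[x_label], s_y=matrices[y_label],
    )


def concat_network(
    ds: ExpressionDataset, center: bool = False
) -> GroupCorrelationNetwork:
    """Correlation of per-group concatenated time series.

    Individuals are concatenated in sorted individual-id order; with
    ``center=True`` each individual's gene-wise mean is subtracted first.
    """
    if center:
        ds = center_individuals(ds)
    x_label, y_label = _two_labels(ds)
    group_of = ds.group_of
    matrices: dict[str, np.ndarray] = {}
    for label in (x_label, y_label):
        members = sorted(i for i in ds.individuals if group_of[i] == label)
        stacked = np.concatenate(
            [ds.individual_matrix(i) for i in members], axis=1
        )
        matrices[label] = _safe_corrcoef(stacked)
    return GroupCorrelationNetwork(
        method="concat", genes=list(ds.genes),
        x_label=x_label, y_label=y_label,
        s_x=matrices[x_label], s_y=matrices[y_label],
        params={"center": center},
    )


def indcorr_network(
    nets: Sequence[IndividualCorrelationNetwork],
    groups: Mapping[str, str],
) -> GroupCorrelationNetwork:
    """Group-wise mean of within-individual raw correlations."""
    if not nets:
        raise ValueError("no individual networks given")
    genes = nets[0].genes
    labels = sorted({groups[n.individual_id] for n in nets})
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    matrices: dict[str, np.ndarray] = {}
    for label in labels:
        member_r = [
            n.r for n in nets if groups[n.individual_id] == label
        ]
        if not member_r:
            raise ValueError(f"group {label!r} has no individuals")
        s = np.mean(member_r, axis=0)
        np.fill_diagonal(s, 0.0)
        matrices[label] = s
    return GroupCorrelationNetwork(
        method="indcorr", genes=list(genes),
        x_label=labels[0], y_label=labels[1],
        s_x=matrices[labels[0]], s_y=matrices[labels[1]],
    )


def connectivity_rank(
    net: GroupCorrelationNetwork, beta: float = 6.0
) -> RankedGeneList:
    """Soft-thresholded differential-connectivity ranking.

    score(g) = sum_{h != g} | |s_X(g,h)|^beta - |s_Y(g,h)|^beta |; descending
    order, ties broken by gene id.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    ax = np.abs(net.s_x) ** beta
    ay = np.abs(net.s_y) ** beta
    scores = np.abs(ax - ay).sum(axis=1)
    return RankedGeneList.from_scores(dict(zip(net.genes, scores)))


class ConnectivityModel:
    """Model wrapper running one baseline strategy end to end.

    Parameters
    ----------
    dataset : ExpressionDataset
    method : {"average", "concat", "indcorr"}
    center : bool
        Per-individual centering before concatenation (concat only).
    beta : float
        Soft-threshold power for the connectivity ranking.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        method: str = "average",
        center: bool = False,
        beta: float = 6.0,
    ) -> None:
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
        self.dataset = dataset
        self.method = method
        self.center = center
        self.beta = beta

    def fit(self) -> "ConnectivityResults":
        if self.method == "average":
            net = average_profile_network(self.dataset)
        elif self.method == "concat":
            net = concat_network(self.dataset, center=self.center)
        else:
            nets = build_all_networks(self.dataset)
            net = indcorr_network(nets, self.dataset.group_of)
        ranking = connectivity_rank(net, beta=self.beta)
        return ConnectivityResults(model=self, network=net, ranking=ranking)


@dataclasses.dataclass
class ConnectivityResults:
    model: ConnectivityModel
    network: GroupCorrelationNetwork
    ranking: RankedGeneList

    @property
    def scores(self):
        import pandas as pd

        t = self.ranking.table
        return pd.Series(
            t["score"].to_numpy(), index=t["gene_id"].to_numpy(), name="score"
        ).reindex(self.network.genes)

    def ranked_list(self) -> RankedGeneList:
        return self.ranking

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Differential connectivity baseline ({self.network.method})",
            "=" * 45,
            f"genes: {len(self.network.genes)}    "
            f"groups: {self.network.x_label} vs {self.network.y_label}    "
            f"beta: {self.model.beta:g}",
            "-" * 45,
            f"{'rank':>4}  {'gene':<12}  {'score':>10}",
        ]
        for row in self.ranking.table.head(top).itertuples(index=False):
            lines.append(f"{row.rank:>4}  {row.gene_id:<12}  {row.score:>10.4f}")
        return "\n".join(lines)
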