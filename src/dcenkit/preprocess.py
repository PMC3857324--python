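"""Gene-filtering transforms applied before network construction.

Three optional steps: collapsing multiple probes mapping to the same gene id
(keeping the probe with the highest overall mean intensity), a non-specific
variance filter retaining the most variable fraction of genes, and
per-individual gene-wise mean centering.  All tie-breaks are lexicographic on
gene id so results are identical across runs and platforms.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping

import numpy as np

from .io import ExpressionDataset

__all__ = [
    "FilterReport",
    "collapse_duplicate_ids",
    "variance_filter",
    "center_individuals",
]


@dataclasses.dataclass
class FilterReport:
    n_input: int
    n_output: int
    rule: str
    removed: list[str]

    def __post_init__(self) -> None:
        if self.n_output != self.n_input - len(self.removed):
            raise ValueError("inconsistent filter report counts")

    def __str__(self) -> str:
        return (
            f"{self.rule}: {self.n_input} -> {self.n_output} genes "
            f"({len(self.removed)} removed)"
        )


def collapse_duplicate_ids(
    ds: ExpressionDataset, id_map: Mapping[str, str]
) -> tuple[ExpressionDataset, FilterReport]:
    """Collapse probe-level rows to one row per mapped gene id.

    For each gene id with several probes the probe with the highest overall
    mean intensity (over all samples) is retained; exact ties go to the
    lexicographically smallest probe id.  Probes absent from ``id_map`` are
    dropped.
    """
    if not id_map:
        raise ValueError("id_map is empty")
    means = ds.values.mean(axis=1)
    # candidate probe per target id: (-mean, probe_id) minimal
    best: dict[str, tuple[float, str, int]] = {}
    unmapped: list[str] = []
    for i, probe in enumerate(ds.genes):
        target = id_map.get(probe)
        if target is None:
            unmapped.append(probe)
            continue
        cand = (-means[i], probe, i)
        if target not in best or cand < best[target]:
            best[target] = cand
    kept_rows = {i for (_, _, i) in best.values()}
    removed = sorted(set(ds.genes) - {ds.genes[i] for i in kept_rows})
    targets = sorted(best)
    idx = [best[t][2] for t in targets]
    out = ExpressionDataset(
        genes=targets, design=ds.design, values=ds.values[idx, :]
    )
    report = FilterReport(
        n_input=ds.n_genes,
        n_output=out.n_genes,
        rule="collapse duplicate ids (highest overall mean intensity)",
        removed=removed,
    )
    return out, report


def variance_filter(
    ds: ExpressionDataset, keep_fraction: float = 0.20
) -> tuple[ExpressionDataset, FilterReport]:
    """Retain the ``keep_fraction`` of genes with the highest overall variance.

    Variance is the population variance (denominator n) over all samples of
    both groups pooled; ``ceil(keep_fraction * n_genes)`` genes are kept.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    variances = ds.values.var(axis=1, ddof=0)
    n_keep = math.ceil(keep_fraction * ds.n_genes)
    if np.allclose(variances, 0):
        warnings.warn(
            "all genes have zero variance; keeping the first genes by id",
            stacklevel=2,
        )
    order = sorted(range(ds.n_genes), key=lambda i: (-variances[i], ds.genes[i]))
    keep = sorted(order[:n_keep])  # preserve original row order
    kept_genes = [ds.genes[i] for i in keep]
    removed = sorted(set(ds.genes) - set(kept_genes))
    out = ExpressionDataset(
        genes=kept_genes, design=ds.design, values=ds.values[keep, :]
    )
    report = FilterReport(
        n_input=ds.n_genes,
        n_output=out.n_genes,
        rule=f"variance filter (keep top {keep_fraction:g} by overall variance)",
        removed=removed,
    )
    return out, report


def center_individuals(ds: ExpressionDataset) -> ExpressionDataset:
    """Subtract each gene's per-individual mean from that individual's values.

    After centering, every (gene, individual) series has mean zero.  Pearson
    correlations within an individual are unchanged; the transform matters for
    the concatenation strategy, where between-individual baseline offsets
    otherwise dominate the pooled correlation.  Idempotent.
    """
    values = ds.values.copy()
    ind = ds.design["individual_id"].to_numpy()
    for individual in ds.individuals:
        cols = ind == individual
        values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    return ds.with_values(values)
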