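"""Data containers and text-format I/O.

The universal input is an :class:`ExpressionDataset`: a gene x sample matrix of
log-scale expression values together with a sample design table mapping each
sample (column) to an individual, a group and a time point.  Every individual
contributes a short time series; within-individual time series are the atomic
objects of the whole analysis, so the dataset validates that each individual
has at least three time points and belongs to exactly one group.

Matrices and designs are plain TSV files; ranked gene lists and co-expression
networks are written as TSV / SIF / GraphML so they can be consumed by
standard graph tooling (e.g. Cytoscape).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("sample_id", "individual_id", "group", "time")

__all__ = [
    "ExpressionDataset",
    "RankedGeneList",
    "read_expression",
    "write_expression",
    "read_ranked_list",
    "write_network",
    "read_network_tsv",
    "DESIGN_COLUMNS",
]


@dataclasses.dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with per-sample design.

    Parameters
    ----------
    genes
        Unique gene identifiers, one per matrix row.
    design
        DataFrame with columns ``sample_id``, ``individual_id``, ``group``,
        ``time``; one row per matrix column, aligned with ``values``.
    values
        Real matrix of shape ``(n_genes, n_samples)``.

    On construction the samples are re-ordered by ``(group, individual, time)``
    so that downstream results do not depend on the column order of the input
    files.
    """

    genes: list[str]
    design: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            dup = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        design = self.design.reset_index(drop=True).copy()
        missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
        if missing:
            raise ValueError(f"design table is missing columns: {missing}")
        design = design.loc[:, list(DESIGN_COLUMNS)]
        design["sample_id"] = design["sample_id"].astype(str)
        design["individual_id"] = design["individual_id"].astype(str)
        design["group"] = design["group"].astype(str)
        design["time"] = pd.to_numeric(design["time"], errors="raise")
        if design["sample_id"].duplicated().any():
            dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in design")

        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (len(self.genes), len(design)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.genes)} genes x {len(design)} samples"
            )
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.genes[g]!r}, sample {design['sample_id'].iloc[s]!r}; "
                "missing values are not supported"
            )

        # one group per individual
        per_ind = design.groupby("individual_id", sort=False)
        for ind, sub in per_ind:
            if sub["group"].nunique() > 1:
                raise ValueError(
                    f"individual {ind!r} appears in more than one group: "
                    f"{sorted(sub['group'].unique())}"
                )
            if len(sub) < 3:
                raise ValueError(
                    f"individual {ind!r} has only {len(sub)} time points; "
                    "at least 3 are required"
                )
            if sub["time"].duplicated().any():
                t = sub.loc[sub["time"].duplicated(), "time"].iloc[0]
                raise ValueError(f"individual {ind!r} has duplicated time {t}")

        order = design.sort_values(
            ["group", "individual_id", "time"], kind="mergesort"
        ).index.to_numpy()
        self.design = design.loc[order].reset_index(drop=True)
        self.values = values[:, order]

    # -- basic views ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.design)

    @property
    def groups(self) -> list[str]:
        return sorted(self.design["group"].unique())

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(self.design["individual_id"]))

    @property
    def group_of(self) -> dict[str, str]:
        """Mapping individual -> group label."""
        return dict(
            self.design.drop_duplicates("individual_id")[
                ["individual_id", "group"]
            ].itertuples(index=False, name=None)
        )

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def individual_matrix(self, individual_id: str) -> np.ndarray:
        """Time-ordered (n_genes, m) value matrix for one individual."""
        mask = (self.design["individual_id"] == individual_id).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown individual {individual_id!r}")
        return self.values[:, mask]  # samples already time-sorted

    def individual_times(self, individual_id: str) -> np.ndarray:
        mask = (self.design["individual_id"] == individual_id).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown individual {individual_id!r}")
        return self.design.loc[mask, "time"].to_numpy(dtype=float)

    # -- derived datasets ----------------------------------------------

    def subset_individuals(self, individual_ids: Iterable[str]) -> "ExpressionDataset":
        keep = set(individual_ids)
        unknown = keep - set(self.individuals)
        if unknown:
            raise KeyError(f"unknown individuals: {sorted(unknown)}")
        mask = self.design["individual_id"].isin(keep).to_numpy()
        return ExpressionDataset(
            genes=list(self.genes),
            design=self.design.loc[mask],
            values=self.values[:, mask],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionDataset(
            genes=[self.genes[i] for i in idx],
            design=self.design,
            values=self.values[idx, :],
        )

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(
            genes=list(self.genes), design=self.design, values=values
        )


@dataclasses.dataclass
class RankedGeneList:
    """Genes ordered by a non-increasing score, ranks 1..N, ties by gene id."""

    table: pd.DataFrame  # columns gene_id, score, rank, p_value

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        required = {"gene_id", "score", "rank"}
        if not required.issubset(t.columns):
            raise ValueError(f"ranked list needs columns {sorted(required)}")
        if "p_value" not in t.columns:
            t["p_value"] = np.nan
        ranks = t["rank"].to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(t) + 1)):
            raise ValueError("ranks must be 1..N without gaps")
        if np.any(np.diff(t["score"].to_numpy()) > 1e-12):
            raise ValueError("scores must be non-increasing with rank")
        self.table = t.loc[:, ["gene_id", "score", "rank", "p_value"]]

    @classmethod
    def from_scores(
        cls,
        scores: Mapping[str, float],
        p_values: Mapping[str, float] | None = None,
    ) -> "RankedGeneList":
        genes = sorted(scores)  # lexicographic tie-break
        order = sorted(genes, key=lambda g: (-scores[g], g))
        table = pd.DataFrame(
            {
                "gene_id": order,
                "score": [scores[g] for g in order],
                "rank": np.arange(1, len(order) + 1),
                "p_value": [
                    (p_values or {}).get(g, np.nan) for g in order
                ],
            }
        )
        return cls(table)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene_id"])

    def top(self, k: int) -> list[str]:
        if k <= 0:
            raise ValueError("k must be positive")
        return list(self.table["gene_id"].iloc[:k])

    def score_of(self, gene: str) -> float:
        row = self.table.loc[self.table["gene_id"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} not in ranked list")
        return float(row["score"].iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# file I/O


def read_expression(matrix_path, design_path) -> ExpressionDataset:
    """Read a TSV expression matrix plus TSV design table.

    The matrix has a header row of sample ids and a first column ``gene_id``;
    the design has exactly the columns ``sample_id``, ``individual_id``,
    ``group``, ``time``.  Every matrix column must appear in the design.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if matrix.columns[0] != "gene_id":
        raise ValueError(
            f"first matrix column must be 'gene_id', got {matrix.columns[0]!r}"
        )
    genes = matrix["gene_id"].tolist()
    sample_ids = [str(c) for c in matrix.columns[1:]]

    design = pd.read_csv(design_path, sep="\t", dtype=str)
    missing_cols = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing_cols:
        raise ValueError(f"design table is missing columns: {missing_cols}")
    known = set(design["sample_id"].astype(str))
    for s in sample_ids:
        if s not in known:
            raise ValueError(f"matrix sample {s!r} missing from design table")
    design = design[design["sample_id"].isin(sample_ids)]

    try:
        values = matrix.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value: {exc}") from exc

    # align design rows to matrix columns; ExpressionDataset re-sorts anyway
    design = design.set_index("sample_id").loc[sample_ids].reset_index()
    return ExpressionDataset(genes=genes, design=design, values=values)


def write_expression(ds: ExpressionDataset, matrix_path, design_path) -> None:
    matrix = pd.DataFrame(
        ds.values, index=pd.Index(ds.genes, name="gene_id"),
        columns=ds.design["sample_id"],
    )
    matrix.to_csv(matrix_path, sep="\t", float_format="%.17g")
    ds.design.to_csv(design_path, sep="\t", index=False)


def read_ranked_list(path) -> RankedGeneList:
    return RankedGeneList(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))


def _check_edges(edges) -> list[tuple[str, str, float]]:
    clean = []
    seen = set()
    for a, b, w in edges:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-loop on {a!r} not allowed")
        key = (min(a, b), max(a, b))
        if key in seen:
            raise ValueError(f"duplicate edge {key}")
        seen.add(key)
        clean.append((a, b, float(w)))
    return clean


def write_network(edges, path, format: str = "tsv") -> None:
    """Write a weighted co-expression edge list.

    ``format`` is one of ``sif`` (Cytoscape simple interaction, interaction
    type ``coexp``), ``graphml`` or ``tsv`` (columns gene_a, gene_b, weight).
    Weights are written with at least 6 significant digits.
    """
    edges = _check_edges(edges)
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, _ in edges:
                fh.write(f"{a}\tcoexp\t{b}\n")
    elif fmt == "graphml":
        graph = nx.Graph()
        for a, b, w in edges:
            graph.add_edge(a, b, weight=round(w, 10))
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for a, b, w in edges:
                fh.write(f"{a}\t{b}\t{w:.10g}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_tsv(path) -> list[tuple[str, str, float]]:
    table = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [
        (r.gene_a, r.gene_b, float(r.weight))
        for r in table.itertuples(index=False)
    ]
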