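"""Synthetic grouped time-series cohorts with timing heterogeneity.

The generator emulates the structure of two-group time-course expression
studies after a non-specific variance filter: most retained genes belong to
a few modules of co-regulated genes following smooth latent trajectories of
a shared biological process, plus a minority of unstructured genes.  Each
individual traverses the process at its own speed and onset: individual i
observes trajectory f at warped times u = speed_i * t + offset_i on a
common nominal grid t in [0, 1], with log-normal speed multipliers and
Gaussian offsets.  On top of the timing warp, each gene responds with an
individual-specific log-normal amplitude (responder strength varies from
individual to individual).  Amplitude heterogeneity is invisible to
within-individual Pearson correlations — scaling a series does not change
r — but it makes each gene's group-mean profile a differently-weighted
average of the individual curves, which is what degrades average-profile
approaches on heterogeneous cohorts.  Gene values are
loading * amplitude * f(u) plus Gaussian observation noise.

Two kinds of group-specific rewiring can be planted, with full ground truth:

* *decoupled* genes follow their module in group X but lose their temporal
  program in group Y — ``decouple_mode="independent"`` replaces the signal
  with independent noise (zero co-expression with everything, the
  unambiguous positive set for recovery metrics), while ``"rewired"`` makes
  the gene follow a different module's trajectory instead;
* an optional *switch* gene follows module A's trajectory in group X and
  module B's in group Y, the pattern the switching-neighborhood view is
  designed to expose.

Because the warp acts in latent time while the nominal grid is shared, the
average-profile baseline remains runnable on every generated cohort.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import ExpressionDataset, RankedGeneList

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "TRAJECTORIES",
    "generate",
    "recovery_metrics",
]


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-10.0 * (u - 0.5)))


def _pulse(u):
    return np.exp(-((u - 0.5) ** 2) / (2 * 0.15**2))


def _down_up_down(u):
    return -np.sin(2 * np.pi * u)


_RAW = {"sigmoid": _sigmoid, "pulse": _pulse, "down_up_down": _down_up_down}

# standardise each trajectory to mean 0, sd 1 over the nominal window [0, 1]
_GRID = np.linspace(0.0, 1.0, 2001)
_NORM = {
    name: (fn(_GRID).mean(), fn(_GRID).std()) for name, fn in _RAW.items()
}


def _trajectory(name: str, u: np.ndarray) -> np.ndarray:
    mu, sd = _NORM[name]
    return (_RAW[name](u) - mu) / sd


TRAJECTORIES = tuple(_RAW)


@dataclasses.dataclass
class ModuleSpec:
    """One module of co-regulated genes: size, latent trajectory, loading sd."""

    size: int
    trajectory: str = "sigmoid"
    loading_sd: float = 0.2


def _default_modules() -> list[ModuleSpec]:
    return [
        ModuleSpec(80, "sigmoid"),
        ModuleSpec(80, "pulse"),
        ModuleSpec(80, "down_up_down"),
    ]


@dataclasses.dataclass
class SyntheticConfig:
    """Cohort layout and noise/heterogeneity parameters.

    Defaults: 300 genes with three 80-gene modules (a variance-filtered
    cohort is module-rich; the remaining 60 genes are unstructured), 6
    individuals per group, 8 time points each, log-speed sd 0.3 and offset
    sd 0.15 for the individual time warps, per-(gene, individual) log-normal
    response amplitudes with sd 0.6, 20 decoupled genes and observation
    noise sd 0.3 (trajectories have unit variance on the nominal window, so
    noise_sd 0.3 keeps within-individual module correlations high).
    """

    n_genes: int = 300
    modules: list[ModuleSpec] = dataclasses.field(
        default_factory=_default_modules
    )
    n_individuals: int = 6  # per group
    m: int = 8              # time points per individual
    log_speed_sd: float = 0.3
    offset_sd: float = 0.15
    amplitude_sd: float = 0.6
    n_decoupled: int = 20
    decouple_mode: str = "independent"
    switch_gene: bool = False
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if self.m < 3:
            raise ValueError(f"m must be >= 3, got {self.m}")
        if self.n_individuals < 1:
            raise ValueError(
                f"n_individuals must be >= 1, got {self.n_individuals}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.log_speed_sd < 0 or self.offset_sd < 0:
            raise ValueError("log_speed_sd and offset_sd must be >= 0")
        if self.amplitude_sd < 0:
            raise ValueError(f"amplitude_sd must be >= 0, got {self.amplitude_sd}")
        if self.decouple_mode not in ("independent", "rewired"):
            raise ValueError(
                "decouple_mode must be 'independent' or 'rewired', "
                f"got {self.decouple_mode!r}"
            )
        if self.decouple_mode == "rewired" and len(self.modules) < 2:
            raise ValueError("decouple_mode: 'rewired' needs at least two modules")
        total = sum(s.size for s in self.modules)
        if total > self.n_genes:
            raise ValueError(
                f"modules: total module size {total} exceeds n_genes "
                f"{self.n_genes}"
            )
        for spec in self.modules:
            if spec.trajectory not in _RAW:
                raise ValueError(
                    f"modules: unknown trajectory {spec.trajectory!r}; "
                    f"choose from {sorted(_RAW)}"
                )
            if spec.size < 1:
                raise ValueError("modules: module size must be >= 1")
        if self.n_decoupled > total:
            raise ValueError(
                f"n_decoupled: {self.n_decoupled} exceeds the "
                f"{total} module genes"
            )
        if self.switch_gene:
            if len(self.modules) < 2:
                raise ValueError("switch_gene: needs at least two modules")
            if total >= self.n_genes:
                raise ValueError(
                    "switch_gene: needs at least one gene outside the modules"
                )


@dataclasses.dataclass
class SyntheticTruth:
    """Planted structure: module membership, warps, decoupled and switch genes."""

    module_of: dict[str, str | None]
    decoupled: set[str]
    warps: dict[str, tuple[float, float]]  # individual -> (speed, offset)
    switch_gene: str | None
    modules: dict[str, list[str]]

    def flags(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([g in self.decoupled for g in genes], dtype=int)


def generate(config: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate one cohort plus its ground truth, reproducibly from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    module_ids = [f"M{k + 1}" for k in range(len(config.modules))]
    module_of: dict[str, str | None] = {g: None for g in genes}
    modules: dict[str, list[str]] = {}
    cursor = 0
    for mid, spec in zip(module_ids, config.modules):
        members = genes[cursor : cursor + spec.size]
        modules[mid] = members
        for g in members:
            module_of[g] = mid
        cursor += spec.size
    module_genes = genes[:cursor]
    background = genes[cursor:]

    loadings = {g: 1.0 for g in genes}
    for mid, spec in zip(module_ids, config.modules):
        for g in modules[mid]:
            loadings[g] = 1.0 + rng.normal(0.0, spec.loading_sd)

    decoupled = set(
        map(str, rng.choice(module_genes, size=config.n_decoupled, replace=False))
    ) if config.n_decoupled else set()

    switch = None
    if config.switch_gene:
        switch = background[0]

    traj_of_module = {
        mid: spec.trajectory
        for mid, spec in zip(module_ids, config.modules)
    }
    t_grid = np.linspace(0.0, 1.0, config.m)
    gene_index = {g: i for i, g in enumerate(genes)}

    rows = []
    columns: list[np.ndarray] = []
    warps: dict[str, tuple[float, float]] = {}
    for group in ("X", "Y"):
        for k in range(config.n_individuals):
            ind = f"{group}{k + 1:02d}"
            speed = float(np.exp(rng.normal(0.0, config.log_speed_sd)))
            offset = float(rng.normal(0.0, config.offset_sd))
            warps[ind] = (speed, offset)
            u = speed * t_grid + offset
            latent = {
                mid: _trajectory(traj_of_module[mid], u) for mid in module_ids
            }
            block = rng.normal(0.0, 1.0, size=(config.n_genes, config.m))
            noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.m))
            amps = np.exp(rng.normal(0.0, config.amplitude_sd, config.n_genes))
            for g in module_genes:
                i = gene_index[g]
                mid = module_of[g]
                if group == "Y" and g in decoupled:
                    if config.decouple_mode == "independent":
                        # program lost: independent fluctuation at noise scale
                        block[i] = rng.normal(0.0, config.noise_sd, config.m)
                        continue
                    # rewired: follow the next module's trajectory instead
                    k_mod = module_ids.index(mid)
                    mid = module_ids[(k_mod + 1) % len(module_ids)]
                block[i] = loadings[g] * amps[i] * latent[mid] + noise[i]
            if switch is not None:
                i = gene_index[switch]
                mid = module_ids[0] if group == "X" else module_ids[1]
                block[i] = amps[i] * latent[mid] + noise[i]
            columns.append(block)
            for j, t in enumerate(t_grid):
                rows.append((f"{ind}_t{j}", ind, group, float(t)))

    design = pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "group", "time"]
    )
    values = np.concatenate(columns, axis=1)
    ds = ExpressionDataset(genes=genes, design=design, values=values)
    truth = SyntheticTruth(
        module_of=module_of,
        decoupled=decoupled,
        warps=warps,
        switch_gene=switch,
        modules=modules,
    )
    return ds, truth


def _extract_scores(result, genes: Sequence[str]) -> np.ndarray:
    if hasattr(result, "scores"):  # DCeNResults / ConnectivityResults
        series = result.scores
        return np.asarray([float(series[g]) for g in genes])
    if isinstance(result, RankedGeneList):
        lookup = dict(
            zip(result.table["gene_id"], result.table["score"])
        )
        return np.asarray([float(lookup[g]) for g in genes])
    if isinstance(result, (pd.Series, Mapping)):
        return np.asarray([float(result[g]) for g in genes])
    raise TypeError(f"cannot extract gene scores from {type(result)!r}")


def recovery_metrics(result, truth: SyntheticTruth) -> tuple[float, float]:
    """AUROC and precision-at-|positives| of a ranking against the truth.

    Positives are the planted decoupled genes.  Ties in the scores count as
    half-correct in the AUROC (rank-sum convention); the top list for the
    precision breaks ties lexicographically on gene id.
    """
    genes = sorted(truth.module_of)
    y = truth.flags(genes)
    if y.sum() == 0:
        raise ValueError("truth has no decoupled (positive) genes")
    scores = _extract_scores(result, genes)
    if y.sum() == len(genes):
        raise ValueError("truth has no negative genes")
    auroc = float(roc_auc_score(y, scores))
    k = int(y.sum())
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    top = order[:k]
    precision = float(np.mean([y[i] for i in top]))
    return auroc, precision
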