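"""Shared fixtures: dataset builders and a brute-force scalar oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import pearsonr

from dcenkit.io import ExpressionDataset

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_dataset(
    n_genes: int = 6,
    n_per_group: int = 3,
    m: int = 5,
    seed: int = 0,
    groups: tuple[str, str] = ("X", "Y"),
    values: np.ndarray | None = None,
) -> ExpressionDataset:
    """Random Gaussian dataset with a regular two-group design."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(1, n_genes + 1)]
    rows = []
    for group in groups:
        for k in range(n_per_group):
            ind = f"{group}{k + 1}"
            for j in range(m):
                rows.append((f"{ind}_t{j}", ind, group, float(j)))
    design = pd.DataFrame(
        rows, columns=["sample_id", "individual_id", "group", "time"]
    )
    if values is None:
        values = rng.normal(size=(n_genes, len(design)))
    return ExpressionDataset(genes=genes, design=design, values=values)


@pytest.fixture
def make_dataset():
    return build_dataset


# ---------------------------------------------------------------------------
# independent scalar re-computation of the whole pipeline (nested loops,
# correlation p-values via scipy.stats.pearsonr's beta-distribution route)


def oracle_dcen_scores(
    ds: ExpressionDataset,
    p_cut: float = 0.05,
    frac: float = 0.25,
    min_count: int = 2,
) -> dict[str, float]:
    genes = ds.genes
    n = len(genes)
    group_of = ds.group_of
    individuals = ds.individuals
    r_all, p_all, w_all = {}, {}, {}
    for ind in individuals:
        vals = ds.individual_matrix(ind)
        for a in range(n):
            for b in range(a + 1, n):
                xa, xb = vals[a], vals[b]
                if np.std(xa) == 0 or np.std(xb) == 0:
                    r, p = 0.0, 1.0
                else:
                    r, p = pearsonr(xa, xb)
                r_all[ind, a, b] = r
                p_all[ind, a, b] = p
                w_all[ind, a, b] = float(np.sign(r) * (1.0 - p))
    labels = sorted(set(group_of.values()))
    members = {
        lab: [i for i in individuals if group_of[i] == lab] for lab in labels
    }
    thresholds = {
        lab: max(
            math.ceil(frac * len(members[lab])),
            min(min_count, len(members[lab])),
            1,
        )
        for lab in labels
    }
    scores = {}
    for g in range(n):
        num = den = 0.0
        for h in range(n):
            if h == g:
                continue
            a, b = min(g, h), max(g, h)
            retained = False
            for lab in labels:
                kp = sum(
                    1
                    for ind in members[lab]
                    if p_all[ind, a, b] < p_cut and r_all[ind, a, b] > 0
                )
                kn = sum(
                    1
                    for ind in members[lab]
                    if p_all[ind, a, b] < p_cut and r_all[ind, a, b] < 0
                )
                if kp >= thresholds[lab] or kn >= thresholds[lab]:
                    retained = True
            if not retained:
                continue
            wbar = {
                lab: sum(w_all[ind, a, b] for ind in members[lab])
                / len(members[lab])
                for lab in labels
            }
            num += abs(wbar[labels[0]] - wbar[labels[1]])
            den += abs(wbar[labels[0]]) + abs(wbar[labels[1]])
        scores[genes[g]] = num / den if den > 0 else 0.0
    return scores
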