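"""Replicate-level and model-level evaluation metrics.

Selection frequencies across simulation replicates, the empirical
false-selection rate under the null, LKMT rejection rates (raw and
Bonferroni-corrected), and prediction metrics (Youden cut point,
misclassification rate, rank-based AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ReplicateResults:
    """Per-replicate pathway selections (and optional LKMT p-values)."""

    pathway_ids: list[str]
    selected: np.ndarray  # replicates x pathways, boolean
    lkmt_p: np.ndarray | None = None  # replicates x pathways
    causal_pathways: list[str] | None = None
    seeds: list[int] | None = None
    m_stops: list[int] | None = None  # tuned m_stop per replicate

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 2 or self.selected.shape[1] != len(self.pathway_ids):
            raise ValueError("selected must be replicates x pathways")
        if self.lkmt_p is not None:
            self.lkmt_p = np.asarray(self.lkmt_p, dtype=float)
            if self.lkmt_p.shape != self.selected.shape:
                raise ValueError("lkmt_p shape must match selected")

    @property
    def n_replicates(self) -> int:
        return self.selected.shape[0]


def selection_frequency(results: ReplicateResults) -> pd.Series:
    """Fraction of replicates in which each pathway entered the model."""
    if results.n_replicates < 1:
        raise ValueError("need at least one replicate")
    return pd.Series(
        results.selected.mean(axis=0), index=results.pathway_ids, name="selection_frequency"
    )


def lkmt_rejection_frequency(
    results: ReplicateResults, alpha: float = 0.05, bonferroni: bool = False
) -> pd.Series:
    """Fraction of replicates in which each pathway was LKMT-significant."""
    if results.lkmt_p is None:
        raise ValueError("results carry no LKMT p-values")
    thresh = alpha / len(results.pathway_ids) if bonferroni else alpha
    name = "lkmt_bonferroni_frequency" if bonferroni else "lkmt_frequency"
    return pd.Series(
        (results.lkmt_p < thresh).mean(axis=0), index=results.pathway_ids, name=name
    )


def false_selection_rate(results: ReplicateResults) -> tuple[float, int]:
    """Percentage of falsely selected (pathway, replicate) pairs under the null.

    Returns ``(rate_percent, n_empty_models)``: 100 times the number of
    selected pairs over (pathways x replicates), plus the count of replicates
    in which no pathway at all entered the tuned model.
    """
    total = results.selected.size
    n_selected = int(results.selected.sum())
    n_empty = int((~results.selected.any(axis=1)).sum())
    return 100.0 * n_selected / total, n_empty


def youden_cutpoint(y: np.ndarray, p_hat: np.ndarray) -> tuple[float, float]:
    """Probability threshold maximizing the Youden index J = sens + spec - 1.

    Candidate cuts are the observed predicted probabilities; individuals with
    ``p_hat >= cut`` are classified as cases.  On ties the smallest cut wins.
    A constant score vector is degenerate: J = 0 with a warning.
    """
    y = np.asarray(y, dtype=int)
    p_hat = np.asarray(p_hat, dtype=float)
    if len(set(np.unique(y)) - {0, 1}) or len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes, coded 0/1")
    cuts = np.unique(p_hat)
    if len(cuts) == 1:
        warnings.warn("constant predicted probabilities; Youden index is 0")
        return float(cuts[0]), 0.0
    pred = p_hat[None, :] >= cuts[:, None]  # cuts x individuals
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    sens = (pred & (y == 1)).sum(axis=1) / n1
    spec = (~pred & (y == 0)).sum(axis=1) / n0
    J = sens + spec - 1.0
    best = int(np.argmax(J))  # first (= smallest cut) on ties
    return float(cuts[best]), float(J[best])


def misclassification_rate(y: np.ndarray, p_hat: np.ndarray, cut: float) -> float:
    """Fraction of individuals whose thresholded prediction differs from y."""
    if not 0 <= cut <= 1:
        raise ValueError("cut must lie in [0, 1]")
    y = np.asarray(y, dtype=int)
    pred = (np.asarray(p_hat, dtype=float) >= cut).astype(int)
    return float(np.mean(pred != y))


def roc_auc(y: np.ndarray, p_hat: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    y = np.asarray(y, dtype=int)
    p_hat = np.asarray(p_hat, dtype=float)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("y must contain both classes")
    ranks = rankdata(p_hat)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
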