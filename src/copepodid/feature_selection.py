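"""Forward stepwise discriminant analysis (FSDA) via Wilks' Lambda.

Given a table of feature columns and a grouping label per row, Wilks'
Lambda for a feature subset is

    Lambda = det(W) / det(T)

where W is the pooled within-group SSCP matrix and T the total SSCP
about the grand mean, both restricted to the subset's columns.  Small
Lambda means strong group separation.  A candidate feature's added
discrimination given p already-entered features is its partial Lambda

    partial = Lambda(current + candidate) / Lambda(current)

and the associated F statistic

    F = ((n - g - p) / (g - 1)) * (1 - partial) / partial

which under the null of no added discrimination is F(g-1, n-g-p).
Forward selection greedily enters the candidate with the largest F as
long as it clears a threshold (default 3.84, the 5% chi-square-1
heuristic).  Selection is purely forward (no backward elimination
pass), and ties are broken by feature-name order so the path is
deterministic.

This module selects features only; classification is done by the
neural network in :mod:`copepodid.ann_classifier`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_F_THRESHOLD = 3.84


class CollinearSubsetError(ValueError):
    """Raised when the within-group SSCP is singular on a subset."""


@dataclass
class FeatureTable:
    """Feature matrix plus group labels, validated for discriminant use."""

    data: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.data) != len(self.labels):
            raise ValueError("data and labels must align")
        if self.data.isna().any().any():
            raise ValueError("missing values not allowed")
        groups, counts = np.unique(self.labels, return_counts=True)
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        if counts.min() < 2:
            raise ValueError("each group needs at least 2 members")
        if len(self.data) <= len(groups):
            raise ValueError("need more rows than groups")
        self.groups = groups

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def g(self) -> int:
        return len(self.groups)


def _sscp(table: FeatureTable, columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) SSCP matrices on the columns."""
    X = table.data[columns].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for grp in table.groups:
        Xg = X[table.labels == grp]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    return W, T


def wilks_lambda(table: FeatureTable, subset) -> float:
    """det(W)/det(T) over the subset's columns, in (0, 1]."""
    subset = list(subset)
    if not subset:
        return 1.0
    W, T = _sscp(table, subset)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or not np.isfinite(logdet_w) or sign_t <= 0:
        raise CollinearSubsetError(f"collinear feature subset: {subset}")
    return float(np.exp(logdet_w - logdet_t))


def f_to_enter(table: FeatureTable, current, candidate: str) -> float:
    """F statistic of the candidate's partial Wilks' Lambda.

    A candidate that is collinear with the entered set adds no
    information and returns F = 0.
    """
    current = list(current)
    if candidate in current:
        raise ValueError(f"candidate {candidate!r} already entered")
    p = len(current)
    df2 = table.n - table.g - p
    if df2 <= 0:
        raise ValueError("insufficient degrees of freedom")
    lam_cur = wilks_lambda(table, current)
    try:
        lam_new = wilks_lambda(table, current + [candidate])
    except CollinearSubsetError:
        return 0.0
    partial = lam_new / lam_cur
    partial = min(partial, 1.0)
    if partial <= 0.0:
        return float("inf")
    return (df2 / (table.g - 1)) * (1.0 - partial) / partial


@dataclass
class StepwiseResults:
    """The selection path produced by :class:`StepwiseDiscriminantAnalysis`.

    ``entered[k]`` was entered at step k with F-to-enter
    ``f_values[k]``, leaving the model at Wilks' Lambda ``lambdas[k]``.
    """

    entered: list[str]
    f_values: list[float]
    lambdas: list[float]
    n: int
    g: int
    f_threshold: float
    candidate_order: list[str] = field(default_factory=list)

    @property
    def p_in_model(self) -> list[int]:
        return list(range(1, len(self.entered) + 1))

    def top(self, k: int) -> list[str]:
        """The k entered features with the largest F at entry."""
        order = np.argsort([-f for f in self.f_values], kind="stable")
        chosen = sorted(order[:k])
        return [self.entered[i] for i in chosen]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.p_in_model,
                "feature": self.entered,
                "F_to_enter": self.f_values,
                "wilks_lambda": self.lambdas,
            }
        )


class StepwiseDiscriminantAnalysis:
    """Greedy forward feature entry maximising F-to-enter.

    Parameters
    ----------
    data : DataFrame
        One row per specimen, one named column per feature.
    labels : array-like
        Group (species) label per row.
    """

    def __init__(self, data: pd.DataFrame, labels) -> None:
        self.table = FeatureTable(data, np.asarray(labels))

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, label_column: str = "species_code"
    ) -> "StepwiseDiscriminantAnalysis":
        feats = frame.drop(columns=[label_column])
        return cls(feats, frame[label_column].to_numpy())

    def fit(
        self,
        f_threshold: float = DEFAULT_F_THRESHOLD,
        max_features: int | None = None,
    ) -> StepwiseResults:
        table = self.table
        candidates = sorted(table.data.columns)  # name order breaks ties
        entered: list[str] = []
        f_path: list[float] = []
        lam_path: list[float] = []
        limit = max_features if max_features is not None else len(candidates)
        while len(entered) < limit:
            remaining = [c for c in candidates if c not in entered]
            if not remaining or table.n - table.g - len(entered) <= 0:
                break
            fs = [f_to_enter(table, entered, c) for c in remaining]
            best = int(np.argmax(fs))  # first max wins -> name-order tie-break
            if fs[best] < f_threshold:
                break
            entered.append(remaining[best])
            f_path.append(float(fs[best]))
            lam_path.append(wilks_lambda(table, entered))
        return StepwiseResults(
            entered=entered,
            f_values=f_path,
            lambdas=lam_path,
            n=table.n,
            g=table.g,
            f_threshold=f_threshold,
            candidate_order=candidates,
        )


def fsda_select(
    data: pd.DataFrame,
    labels,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    max_features: int | None = None,
) -> StepwiseResults:
    """Functional wrapper around :class:`StepwiseDiscriminantAnalysis`."""
    return StepwiseDiscriminantAnalysis(data, labels).fit(f_threshold, max_features)
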