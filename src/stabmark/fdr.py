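"""FDR-adjusted selection: the comparator to stability selection.

Benjamini-Hochberg step-up adjustment of per-variable p-values, with
selection at adjusted p strictly below the level (default 0.05). For the
t test the raw p-values are analytic; for VIP scores, where no analytic
null exists, they come from a group-label permutation null with add-one
correction:

    p_j = (1 + #{permutations with VIP_j* >= VIP_j}) / (1 + n_perm)

The permutation mechanism is this package's interpretive choice — see
docs/methods.md — since a VIP score has no canonical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LabeledMatrix
from .selectors import plsda_vip, ttest_scores
from .stability import SelectionResult

__all__ = [
    "AdjustedPValues",
    "bh_adjust",
    "vip_null_pvalues",
    "fdr_select",
    "FDRSelection",
]

FDR_METHODS = ("ttest", "vip")


@dataclass
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    level: float = 0.05

    def reject(self) -> np.ndarray:
        """Boolean mask of variables with adjusted p strictly below level."""
        return self.adjusted < self.level


def bh_adjust(raw: np.ndarray, level: float = 0.05) -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjusted p-values.

    With order statistics p_(1) <= ... <= p_(m), the adjusted value for
    p_(i) is min_{j >= i} min(1, m * p_(j) / j).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size == 0:
        raise ValueError("raw must be a non-empty 1-d vector")
    if np.any((raw < 0) | (raw > 1) | ~np.isfinite(raw)):
        raise ValueError("p-values must lie in [0, 1]")
    m = raw.size
    order = np.argsort(raw, kind="stable")
    scaled = raw[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustedPValues(raw=raw, adjusted=adjusted, level=level)


def vip_null_pvalues(
    data: LabeledMatrix,
    ncomp: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for VIP scores by shuffling group labels.

    The add-one estimator bounds the attainable minimum at 1/(1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    counts = data.group_sizes()
    if min(counts) == 0:
        raise ValueError("both groups must be non-empty")
    observed = plsda_vip(data, ncomp=ncomp).scores
    rng = np.random.default_rng(seed)
    exceed = np.zeros(data.p)
    for _ in range(n_perm):
        permuted = LabeledMatrix(
            X=data.X,
            y=rng.permutation(data.y),
            var_names=data.var_names,
            truth=data.truth,
        )
        exceed += plsda_vip(permuted, ncomp=ncomp).scores >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def fdr_select(
    data: LabeledMatrix,
    method: str,
    level: float = 0.05,
    ncomp: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> SelectionResult:
    """BH-adjusted selection at adjusted p < level (strict).

    Ranking is by adjusted p ascending, ties broken by raw p, then by score
    descending, then by index, so the result carries a strict full ranking
    for ROC construction.
    """
    if method not in FDR_METHODS:
        raise ValueError(f"method must be one of {FDR_METHODS}, got {method!r}")
    if method == "ttest":
        base = ttest_scores(data)
        raw = base.pvalues
    else:
        base = plsda_vip(data, ncomp=ncomp)
        raw = vip_null_pvalues(data, ncomp=ncomp, n_perm=n_perm, seed=seed)
    adj = bh_adjust(raw, level=level)
    p = data.p
    ranking = np.lexsort((np.arange(p), -base.scores, raw, adj.adjusted))
    selected = ranking[adj.adjusted[ranking] < level]
    return SelectionResult(
        method=f"fdr_{method}",
        ranking=ranking,
        selected=selected,
        criterion=adj.adjusted,
        criterion_name="adjusted_pvalue",
        var_names=data.var_names,
        meta={
            "raw_pvalues": raw,
            "scores": base.scores,
            "level": level,
            "n_perm": n_perm if method == "vip" else None,
        },
    )


class FDRSelection:
    """FDR-adjusted selection model (t test or permutation VIP).

    Mirrors :class:`stabmark.stability.StabilitySelection`: construct from a
    :class:`LabeledMatrix` (or a data frame with a group column) and call
    :meth:`fit` to obtain a :class:`SelectionResult`.
    """

    def __init__(
        self,
        data: LabeledMatrix,
        method: str = "ttest",
        level: float = 0.05,
        ncomp: int = 2,
        n_perm: int = 1000,
        seed: int = 0,
    ) -> None:
        if method not in FDR_METHODS:
            raise ValueError(f"method must be one of {FDR_METHODS}, got {method!r}")
        self.data = data
        self.method = method
        self.level = level
        self.ncomp = ncomp
        self.n_perm = n_perm
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group", **kwargs) -> "FDRSelection":
        y = df[group_col].to_numpy()
        X = df.drop(columns=[c for c in (group_col, "sample_id") if c in df.columns])
        data = LabeledMatrix(
            X=X.to_numpy(float), y=y, var_names=np.array(X.columns, dtype=object)
        )
        return cls(data, **kwargs)

    def fit(self) -> SelectionResult:
        return fdr_select(
            self.data,
            self.method,
            level=self.level,
            ncomp=self.ncomp,
            n_perm=self.n_perm,
            seed=self.seed,
        )
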