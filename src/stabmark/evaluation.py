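"""Variable-level ROC curves, partial AUC and bootstrap summaries.

The ROC here is over *variables*, not samples: a method's full ranking is
walked from most to least important, each true biomarker encountered moves
the true-positive fraction up by 1/n_true and each non-biomarker moves the
false-positive fraction right by 1/n_false. The partial AUC integrates the
resulting right-continuous step curve over false-positive fractions up to
``fpr_max`` (default 0.2, i.e. specificity >= 80%).

Two pAUC normalisations are exposed: ``proportional`` (raw / fpr_max, the
package default) and ``mcclish`` (linear map placing the chance diagonal at
0.5 and the perfect curve at 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROCCurve",
    "PaucResult",
    "roc_from_ranking",
    "pauc",
    "operating_point",
    "bootstrap_median_ci",
]

CONVENTIONS = ("proportional", "mcclish")


@dataclass
class ROCCurve:
    """Step ROC over a variable ranking; points start at (0, 0)."""

    fpr: np.ndarray
    tpr: np.ndarray
    n_true: int
    n_false: int

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass
class PaucResult:
    fpr_max: float
    raw: float
    normalized: float
    convention: str


def roc_from_ranking(ranking: np.ndarray, truth: np.ndarray) -> ROCCurve:
    """Walk a strict full ranking against a ground-truth biomarker mask."""
    truth = np.asarray(truth, dtype=bool)
    ranking = np.asarray(ranking)
    p = truth.size
    if sorted(ranking.tolist()) != list(range(p)):
        raise ValueError("ranking must be a permutation of all variable indices")
    n_true = int(truth.sum())
    n_false = p - n_true
    if n_true == 0 or n_false == 0:
        raise ValueError("truth mask must contain at least one true and one false variable")
    hits = truth[ranking]
    tpr = np.concatenate(([0.0], np.cumsum(hits) / n_true))
    fpr = np.concatenate(([0.0], np.cumsum(~hits) / n_false))
    return ROCCurve(fpr=fpr, tpr=tpr, n_true=n_true, n_false=n_false)


def pauc(curve: ROCCurve, fpr_max: float = 0.2, convention: str = "proportional") -> PaucResult:
    """Partial AUC of the step curve over fpr in [0, fpr_max].

    ``raw`` lies in [0, fpr_max]; ``proportional`` rescales to [0, 1] by
    dividing by ``fpr_max``; ``mcclish`` maps chance to 0.5 via
    0.5 * (1 + (raw - fpr_max^2/2) / (fpr_max - fpr_max^2/2)).
    """
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError(f"fpr_max must lie in (0, 1], got {fpr_max}")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    # staircase: for each distinct fpr take the maximum tpr attained there
    fpr, tpr = curve.fpr, curve.tpr
    uniq, last_idx = np.unique(fpr[::-1], return_index=True)
    step_tpr = tpr[::-1][last_idx]  # np.unique sorts ascending; last occurrence = max tpr
    # integrate tpr over [uniq[i], uniq[i+1]) clipped to fpr_max
    rights = np.append(uniq[1:], max(1.0, fpr_max))
    widths = np.clip(np.minimum(rights, fpr_max) - uniq, 0.0, None)
    raw = float(np.sum(step_tpr * widths))
    if convention == "proportional":
        normalized = raw / fpr_max
    else:
        chance = fpr_max**2 / 2.0
        normalized = 0.5 * (1.0 + (raw - chance) / (fpr_max - chance))
    return PaucResult(fpr_max=fpr_max, raw=raw, normalized=normalized, convention=convention)


def operating_point(selected: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(sensitivity, 1 - specificity) of a selected set of variable indices.

    sensitivity = selected true biomarkers / all true biomarkers;
    1 - specificity = selected non-biomarkers / all non-biomarkers.
    """
    truth = np.asarray(truth, dtype=bool)
    selected = np.asarray(selected, dtype=int)
    n_true = int(truth.sum())
    n_false = truth.size - n_true
    if n_true == 0 or n_false == 0:
        raise ValueError("truth mask must contain at least one true and one false variable")
    if selected.size == 0:
        return 0.0, 0.0
    hits = truth[selected]
    return float(hits.sum() / n_true), float((~hits).sum() / n_false)


def operating_point_names(
    selected_names, truth_names, var_names
) -> tuple[float, float]:
    """Name-based convenience wrapper around :func:`operating_point`."""
    var_names = list(var_names)
    index = {v: i for i, v in enumerate(var_names)}
    truth = np.array([v in set(truth_names) for v in var_names])
    selected = np.array([index[v] for v in selected_names], dtype=int)
    return operating_point(selected, truth)


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Basic (reverse-percentile) bootstrap CI for the median.

    (2*m - q_{1-a/2}, 2*m - q_{a/2}) with m the sample median and q the
    quantiles of the bootstrap distribution of resampled medians.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = np.median(values[idx], axis=1)
    m = float(np.median(values))
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    return 2.0 * m - float(q_hi), 2.0 * m - float(q_lo)
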