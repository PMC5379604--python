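"""Stability-based secondary selection by data perturbation.

The engine repeatedly perturbs a dataset — removing an out-of-bag fraction
of samples from each group and keeping a random fraction of the variables —
re-runs a base selector on each perturbed dataset, and records how often
each variable lands in the selector's top ``ntop``. A variable is selected
when that stability fraction reaches ``min_present`` (>= , "at least half"
at the default 0.5). The fraction's denominator counts only perturbations
in which the variable was actually included, so variable subsampling does
not bias it downward.

The full-ranking output (stability fraction first, mean base score over
inclusions second) makes the result directly usable for variable-level ROC
construction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import LabeledMatrix, _round_half_even
from .selectors import METHOD_NAMES, get_selector

__all__ = [
    "StabilityConfig",
    "SelectionResult",
    "perturb",
    "stability_select",
    "StabilitySelection",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StabilityConfig:
    """Perturbation-engine parameters.

    ``oob_fraction`` is the fraction of samples removed from each group per
    perturbation; ``variable_fraction`` the fraction of variables kept.
    Counts are rounded half-to-even.
    """

    n_perturb: int = 200
    ntop: int = 10
    min_present: float = 0.5
    variable_fraction: float = 0.5
    oob_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perturb < 1:
            raise ValueError("n_perturb must be positive")
        if self.ntop < 1:
            raise ValueError("ntop must be positive")
        if not 0.0 < self.min_present <= 1.0:
            raise ValueError("min_present must lie in (0, 1]")
        if not 0.0 < self.variable_fraction <= 1.0:
            raise ValueError("variable_fraction must lie in (0, 1]")
        if not 0.0 <= self.oob_fraction < 1.0:
            raise ValueError("oob_fraction must lie in [0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    def n_vars_kept(self, p: int) -> int:
        return max(1, _round_half_even(self.variable_fraction * p))

    def validate_for(self, data: LabeledMatrix) -> None:
        """Reject configurations that would leave degenerate perturbations."""
        for n_g in data.group_sizes():
            if n_g - _round_half_even(self.oob_fraction * n_g) < 2:
                raise ValueError(
                    f"oob_fraction={self.oob_fraction} leaves fewer than 2 "
                    f"samples in a group of size {n_g}"
                )
        if self.ntop > self.n_vars_kept(data.p):
            raise ValueError(
                f"ntop={self.ntop} exceeds the {self.n_vars_kept(data.p)} "
                "variables kept per perturbation"
            )

    def replace(self, **kwargs) -> "StabilityConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SelectionResult:
    """Outcome of a secondary-selection method.

    ``ranking`` is a strict permutation of all variable indices (most to
    least important); ``selected`` is an ordered prefix-consistent subset of
    it. ``criterion`` holds the per-variable selection criterion — the
    stability fraction in [0, 1] for stability methods, the BH-adjusted
    p-value for FDR methods — named by ``criterion_name``.
    """

    method: str
    ranking: np.ndarray
    selected: np.ndarray
    criterion: np.ndarray
    criterion_name: str
    var_names: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def selected_names(self) -> list[str]:
        if self.var_names is None:
            return [str(i) for i in self.selected]
        return [str(v) for v in self.var_names[self.selected]]

    def summary(self, max_rows: int | None = 20) -> pd.DataFrame:
        """Ranked table of variables with the selection criterion."""
        names = (
            self.var_names[self.ranking]
            if self.var_names is not None
            else self.ranking.astype(str)
        )
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking) + 1),
                "variable": names,
                self.criterion_name: self.criterion[self.ranking],
                "selected": np.isin(self.ranking, self.selected),
            }
        )
        return df if max_rows is None else df.head(max_rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SelectionResult {self.method}: {len(self.selected)} of "
            f"{len(self.ranking)} variables selected>"
        )


def _perturb_rng(config: StabilityConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index]))


def perturb(
    data: LabeledMatrix, config: StabilityConfig, index: int
) -> tuple[LabeledMatrix, np.ndarray, np.ndarray]:
    """One perturbed dataset: subsample rows per group and variables.

    Returns ``(subset, rows, cols)`` where ``rows``/``cols`` index into the
    original data. Reproducible from ``(config.seed, index)``.
    """
    rng = _perturb_rng(config, index)
    rows = []
    for g in (0, 1):
        idx = np.flatnonzero(data.y == g)
        n_remove = _round_half_even(config.oob_fraction * len(idx))
        kept = rng.choice(idx, size=len(idx) - n_remove, replace=False)
        rows.append(np.sort(kept))
    rows = np.concatenate(rows)
    cols = np.sort(rng.choice(data.p, size=config.n_vars_kept(data.p), replace=False))
    return data.subset(rows, cols), rows, cols


def stability_select(
    data: LabeledMatrix,
    base: str,
    k_target: int | None = None,
    config: StabilityConfig | None = None,
) -> SelectionResult:
    """Run stability selection with a base selector.

    ``k_target`` is the size at which the path selectors (lasso/enet) stop
    descending the regularisation path; inside a perturbation it is capped
    at twice ``ntop`` and at the number of included variables. It is ignored
    by the t-test and VIP selectors.

    A base-selector failure on a perturbation is retried once on a fresh
    subset and then skipped with a warning; skips are counted in ``meta``.
    """
    if base not in METHOD_NAMES:
        raise ValueError(f"unknown base selector {base!r}; expected one of {METHOD_NAMES}")
    config = config or StabilityConfig()
    config.validate_for(data)
    selector = get_selector(base)
    p = data.p
    if k_target is None:
        k_target = config.ntop
    top_counts = np.zeros(p)
    incl_counts = np.zeros(p)
    score_sums = np.zeros(p)
    n_skipped = 0
    for i in range(config.n_perturb):
        for attempt, idx in enumerate((i, config.n_perturb + i)):
            sub, _, cols = perturb(data, config, idx)
            k_eff = min(k_target, 2 * config.ntop, len(cols))
            try:
                scores = selector(sub, max(1, k_eff))
            except Exception as exc:  # noqa: BLE001 - engine must survive a bad subset
                if attempt == 1:
                    n_skipped += 1
                    logger.warning("perturbation %d skipped after retry: %s", i, exc)
                continue
            top_local = scores.ranking[: config.ntop]
            incl_counts[cols] += 1
            top_counts[cols[top_local]] += 1
            score_sums[cols] += scores.scores
            break
    with np.errstate(invalid="ignore"):
        fraction = np.where(incl_counts > 0, top_counts / np.maximum(incl_counts, 1), 0.0)
        mean_score = np.where(incl_counts > 0, score_sums / np.maximum(incl_counts, 1), -np.inf)
    ranking = np.lexsort((np.arange(p), -mean_score, -fraction))
    selected = ranking[fraction[ranking] >= config.min_present]
    return SelectionResult(
        method=f"stability_{base}",
        ranking=ranking,
        selected=selected,
        criterion=fraction,
        criterion_name="stability_fraction",
        var_names=data.var_names,
        meta={
            "base": base,
            "k_target": k_target,
            "config": config,
            "n_skipped": n_skipped,
            "mean_score": mean_score,
            "inclusions": incl_counts,
        },
    )


class StabilitySelection:
    """Stability-selection model for a labelled two-group matrix.

    Parameters
    ----------
    data : LabeledMatrix
        Samples-by-variables matrix with 0/1 group labels, assumed already
        log-transformed and autoscaled.
    base : {"ttest", "vip", "lasso", "enet"}
        Base importance measure re-fitted on every perturbation.
    k_target : int, optional
        Path-descent target for lasso/enet (typically the expected number of
        biomarkers); ignored by ttest/vip.
    config : StabilityConfig, optional
        Perturbation-engine parameters.

    Examples
    --------
    >>> from stabmark import datasets, StabilitySelection
    >>> data = datasets.spiked_fixture(seed=1)
    >>> res = StabilitySelection(data, base="vip").fit()
    >>> res.summary().head()  # doctest: +SKIP
    """

    def __init__(
        self,
        data: LabeledMatrix,
        base: str = "vip",
        k_target: int | None = None,
        config: StabilityConfig | None = None,
    ) -> None:
        self.data = data
        self.base = base
        self.k_target = k_target
        self.config = config or StabilityConfig()
        self.config.validate_for(data)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, group_col: str = "group", **kwargs
    ) -> "StabilitySelection":
        y = df[group_col].to_numpy()
        X = df.drop(columns=[c for c in (group_col, "sample_id") if c in df.columns])
        data = LabeledMatrix(
            X=X.to_numpy(float), y=y, var_names=np.array(X.columns, dtype=object)
        )
        return cls(data, **kwargs)

    def fit(self) -> SelectionResult:
        return stability_select(self.data, self.base, self.k_target, self.config)
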