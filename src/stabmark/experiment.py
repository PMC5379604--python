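"""Benchmark orchestration: methods x simulation grid x replicates.

Runs the six selection methods (four stability-based, two FDR-adjusted)
over a factorial grid of simulation configurations, evaluates each
replicate's full ranking by normalized pAUC at false-positive fraction 0.2
and each selected set by its operating point, and aggregates per-cell
medians with basic-bootstrap 95% CIs.

Per-replicate seeds are derived deterministically from
``SeedSequence([base_seed, cell_index, replicate, stream])`` so partial
re-runs and parallel schedules reproduce the same tables.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fdr as fdr_mod
from .datasets import CorrelationSpec, LabeledMatrix, SimulationConfig, simulate_dataset
from .evaluation import bootstrap_median_ci, operating_point, pauc, roc_from_ranking
from .stability import SelectionResult, StabilityConfig, stability_select

__all__ = [
    "ALL_METHODS",
    "ExperimentGrid",
    "ResultsTable",
    "run_method",
    "run_cell",
    "run_grid",
    "compare_methods",
    "delta_ratio",
    "preset_grid",
]

logger = logging.getLogger(__name__)

ALL_METHODS = (
    "stability_ttest",
    "stability_vip",
    "stability_lasso",
    "stability_enet",
    "fdr_ttest",
    "fdr_vip",
)

_CELL_COLS = ["n_total", "p", "q", "delta", "correlation"]


def _derive_seed(base_seed: int, *words: int) -> int:
    """Stable sub-2^31 seed from a base seed and integer context words."""
    ss = np.random.SeedSequence([int(base_seed), *[int(w) for w in words]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_method(
    data: LabeledMatrix,
    method: str,
    k_target: int,
    stability: StabilityConfig,
    fdr_level: float = 0.05,
    vip_nperm: int = 1000,
    seed: int = 0,
) -> SelectionResult:
    """Dispatch one of the six benchmark methods on one dataset."""
    if method.startswith("stability_"):
        base = method.removeprefix("stability_")
        return stability_select(data, base, k_target, stability.replace(seed=seed))
    if method.startswith("fdr_"):
        name = method.removeprefix("fdr_")
        return fdr_mod.fdr_select(data, name, level=fdr_level, n_perm=vip_nperm, seed=seed)
    raise ValueError(f"unknown method {method!r}; expected one of {ALL_METHODS}")


def run_cell(
    config: SimulationConfig,
    methods=ALL_METHODS,
    n_replicates: int = 200,
    stability: StabilityConfig | None = None,
    fdr_level: float = 0.05,
    vip_nperm: int = 1000,
    fpr_max: float = 0.2,
    convention: str = "proportional",
    cell_index: int = 0,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Long-format results for one grid cell.

    One row per (method, replicate) with normalized pAUC of the full
    ranking, operating-point sensitivity and 1-specificity of the selected
    set, and the selected-set size. A method failure on a replicate is
    recorded with its reason and excluded from aggregation.
    """
    stability = stability or StabilityConfig()
    k_target = config.n_significant
    rows = []
    t0 = time.perf_counter()
    for rep in range(n_replicates):
        sim_seed = _derive_seed(base_seed, cell_index, rep, 0)
        data = simulate_dataset(config.replace(seed=sim_seed))
        for m, method in enumerate(methods):
            rec = {
                "n_total": config.n_total,
                "p": config.p,
                "q": config.q,
                "delta": config.delta,
                "correlation": config.correlation.structure,
                "method": method,
                "replicate": rep,
            }
            try:
                method_seed = _derive_seed(base_seed, cell_index, rep, m + 1)
                result = run_method(
                    data, method, k_target, stability,
                    fdr_level=fdr_level, vip_nperm=vip_nperm, seed=method_seed,
                )
                curve = roc_from_ranking(result.ranking, data.truth)
                pr = pauc(curve, fpr_max=fpr_max, convention=convention)
                sens, oms = operating_point(result.selected, data.truth)
                rec.update(
                    pauc_normalized=pr.normalized,
                    pauc_raw=pr.raw,
                    sensitivity=sens,
                    one_minus_specificity=oms,
                    n_selected=len(result.selected),
                    error="",
                )
            except Exception as exc:  # noqa: BLE001 - record and continue
                logger.warning("method %s failed on replicate %d: %s", method, rep, exc)
                rec.update(
                    pauc_normalized=np.nan,
                    pauc_raw=np.nan,
                    sensitivity=np.nan,
                    one_minus_specificity=np.nan,
                    n_selected=0,
                    error=str(exc),
                )
            rows.append(rec)
    logger.info(
        "cell %d (N=%d P=%d Q=%.2f d=%.2f %s): %d replicates in %.1fs",
        cell_index, config.n_total, config.p, config.q, config.delta,
        config.correlation.structure, n_replicates, time.perf_counter() - t0,
    )
    return pd.DataFrame(rows)


def aggregate(long: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-(cell, method) medians with basic-bootstrap 95% CIs.

    Failed replicates are dropped; ``n_ok`` reports how many contributed.
    """
    out = []
    for i, (key, grp) in enumerate(long.groupby(_CELL_COLS + ["method"], sort=True)):
        vals = grp["pauc_normalized"].dropna().to_numpy()
        rec = dict(zip(_CELL_COLS + ["method"], key))
        rec["n_ok"] = len(vals)
        if len(vals) >= 2:
            lo, hi = bootstrap_median_ci(vals, n_boot=n_boot, seed=_derive_seed(seed, i))
            rec.update(
                median_pauc=float(np.median(vals)), ci_lower=lo, ci_upper=hi,
                median_sensitivity=float(grp["sensitivity"].median()),
            )
        else:
            rec.update(median_pauc=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                       median_sensitivity=np.nan)
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class ResultsTable:
    """Long per-replicate table plus the per-cell aggregate table."""

    long: pd.DataFrame
    aggregate: pd.DataFrame

    def to_csv(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.long.to_csv(directory / "results_long.csv", index=False)
        self.aggregate.to_csv(directory / "results_aggregate.csv", index=False)


@dataclass
class ExperimentGrid:
    """Full cross product of simulation factors, methods and replicates."""

    n_totals: tuple = (50, 100)
    ps: tuple = (50, 200, 1000)
    qs: tuple = (0.1, 0.2, 0.3)
    deltas: tuple = (0.2, 0.4, 0.8)
    correlations: tuple = (
        CorrelationSpec("independent"),
        CorrelationSpec("ar1"),
        CorrelationSpec("block"),
    )
    methods: tuple = ALL_METHODS
    n_replicates: int = 200
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    fdr_level: float = 0.05
    vip_nperm: int = 1000
    fpr_max: float = 0.2
    base_seed: int = 0

    def cells(self) -> list[SimulationConfig]:
        if not (self.n_totals and self.ps and self.qs and self.deltas and self.correlations):
            raise ValueError("empty grid")
        return [
            SimulationConfig(n_total=n, p=p, q=q, delta=d, correlation=c)
            for n, p, q, d, c in itertools.product(
                self.n_totals, self.ps, self.qs, self.deltas, self.correlations
            )
        ]

    def replace(self, **kwargs) -> "ExperimentGrid":
        return dataclasses.replace(self, **kwargs)


def run_grid(grid: ExperimentGrid) -> ResultsTable:
    """Run every cell of the grid and aggregate.

    The full default grid (162 cells x 200 replicates) is a long-running
    batch job; reduced modes come from shrinking ``n_replicates``,
    ``stability.n_perturb`` and the factor lists (see ``preset_grid``).
    """
    frames = [
        run_cell(
            cfg,
            methods=grid.methods,
            n_replicates=grid.n_replicates,
            stability=grid.stability,
            fdr_level=grid.fdr_level,
            vip_nperm=grid.vip_nperm,
            fpr_max=grid.fpr_max,
            cell_index=i,
            base_seed=grid.base_seed,
        )
        for i, cfg in enumerate(grid.cells())
    ]
    long = pd.concat(frames, ignore_index=True)
    return ResultsTable(long=long, aggregate=aggregate(long, seed=grid.base_seed))


def preset_grid(name: str, **overrides) -> ExperimentGrid:
    """Named benchmark presets.

    - ``full-benchmark``: the complete factorial (162 cells, 200 replicates).
    - ``small-sample``: P = 1000, delta = 0.4, N in {20, 50, 100} (27 cells),
      probing very small per-group sample sizes.
    - ``smoke``: one tiny cell for end-to-end checks.
    """
    if name == "full-benchmark":
        grid = ExperimentGrid()
    elif name == "small-sample":
        grid = ExperimentGrid(n_totals=(20, 50, 100), ps=(1000,), deltas=(0.4,))
    elif name == "smoke":
        grid = ExperimentGrid(
            n_totals=(50,), ps=(30,), qs=(0.1,), deltas=(0.8,),
            correlations=(CorrelationSpec("independent"),),
            n_replicates=3,
            stability=StabilityConfig(n_perturb=25),
            vip_nperm=100,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return grid.replace(**overrides) if overrides else grid


def _cell_medians(agg: pd.DataFrame, cell: dict) -> pd.Series:
    sub = agg
    for col, val in cell.items():
        sub = sub[sub[col] == val]
    if sub.empty:
        raise ValueError(f"no aggregate rows match cell selector {cell}")
    return sub.set_index("method")["median_pauc"]


def compare_methods(
    results: ResultsTable | pd.DataFrame,
    cell: dict,
    group_a,
    group_b,
) -> float:
    """Median-pAUC gap between two method groups in one cell.

    Returns min(median over group_a) - max(median over group_b): the
    worst-case advantage of every method in A over every method in B.
    """
    agg = results.aggregate if isinstance(results, ResultsTable) else results
    med = _cell_medians(agg, cell)
    missing = [m for m in list(group_a) + list(group_b) if m not in med.index]
    if missing:
        raise ValueError(f"methods missing from results: {missing}")
    return float(med[list(group_a)].min() - med[list(group_b)].max())


def delta_ratio(
    results: ResultsTable | pd.DataFrame,
    cell: dict,
    method: str,
    delta_num: float,
    delta_den: float,
) -> float:
    """Ratio of a method's median pAUC between two effect-size levels."""
    agg = results.aggregate if isinstance(results, ResultsTable) else results
    num = _cell_medians(agg, {**cell, "delta": delta_num})[method]
    den = _cell_medians(agg, {**cell, "delta": delta_den})[method]
    return float(num / den)


def plot_pauc_vs_q(agg: pd.DataFrame, n_total: int, p: int, delta: float, ax=None):
    """pAUC-versus-Q panel figure: one panel per correlation structure."""
    import matplotlib.pyplot as plt

    sub = agg[(agg.n_total == n_total) & (agg.p == p) & (agg.delta == delta)]
    structures = sorted(sub["correlation"].unique())
    fig, axes = plt.subplots(1, len(structures), figsize=(4 * len(structures), 3.2),
                             sharey=True, squeeze=False)
    for ax_, corr in zip(axes[0], structures):
        panel = sub[sub["correlation"] == corr]
        for method, grp in panel.groupby("method"):
            grp = grp.sort_values("q")
            med = grp["median_pauc"].to_numpy()
            ax_.errorbar(
                grp["q"].to_numpy(), med,
                yerr=[med - grp["ci_lower"].to_numpy(), grp["ci_upper"].to_numpy() - med],
                marker="o", capsize=2, label=method,
            )
        ax_.set_title(f"{corr} (N={n_total}, P={p}, Δ={delta})")
        ax_.set_xlabel("proportion of significant variables Q")
    axes[0][0].set_ylabel("median normalized pAUC")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    return fig
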