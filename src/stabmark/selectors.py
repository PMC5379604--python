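"""Base per-variable importance measures for two-group data.

Four selectors are provided, all returning a :class:`SelectorScores` with a
full importance vector (larger = more important) and the implied strict
ranking of all variables:

- ``ttest_scores``: absolute two-sample t statistic (pooled variance by
  default, Welch by flag) with two-sided p-values;
- ``plsda_vip``: Variable Importance in Projection from a two-component
  PLS-DA model (NIPALS PLS1, class membership coded 0/1 and autoscaled);
- ``lasso_select`` / ``enet_select``: regularisation-path selectors with
  squared loss on the class codes; variables are ranked by the order in
  which they enter the path, and the operating lambda is the largest one
  whose active set first reaches the requested size (or, failing that, the
  lambda maximising the active-set size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import LabeledMatrix

__all__ = [
    "SelectorScores",
    "ttest_scores",
    "plsda_vip",
    "lasso_select",
    "enet_select",
    "get_selector",
]

logger = logging.getLogger(__name__)

METHOD_NAMES = ("ttest", "vip", "lasso", "enet")


@dataclass
class SelectorScores:
    """Per-variable importance from one base selector.

    ``ranking`` is a strict permutation of variable indices, most important
    first (score descending, ties broken by original index so that every
    downstream ROC walk is well defined). Path selectors give score 0 to
    variables that never enter the path.
    """

    method: str
    scores: np.ndarray
    ranking: np.ndarray
    pvalues: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def top(self, k: int) -> np.ndarray:
        return self.ranking[:k]


def _rank_desc(scores: np.ndarray) -> np.ndarray:
    """Indices ordered by score descending, ties by index ascending."""
    p = scores.shape[0]
    return np.lexsort((np.arange(p), -scores))


def _split_groups(data: LabeledMatrix) -> tuple[np.ndarray, np.ndarray]:
    X0 = data.X[data.y == 0]
    X1 = data.X[data.y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError(
            f"both groups need >= 2 samples, got ({len(X0)}, {len(X1)})"
        )
    return X0, X1


def ttest_scores(data: LabeledMatrix, equal_var: bool = True) -> SelectorScores:
    """Two-sample t statistic per variable; scores are |t|.

    Pooled-variance (classical) by default; set ``equal_var=False`` for
    Welch. Variables with zero variance in both groups score 0 (p = 1) when
    the group means agree, and receive a finite surrogate score larger than
    every regular |t| (p = 0) when they differ.
    """
    X0, X1 = _split_groups(data)
    n0, n1 = len(X0), len(X1)
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    v0 = X0.var(axis=0, ddof=1)
    v1 = X1.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
        se2 = sp2 * (1.0 / n0 + 1.0 / n1)
        df = np.full_like(se2, n0 + n1 - 2)
    else:
        se2 = v0 / n0 + v1 / n1
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    scores = np.abs(t)
    degenerate = se2 == 0
    if np.any(degenerate):
        logger.warning("%d variable(s) with zero within-group variance", degenerate.sum())
        equal_mean = degenerate & (diff == 0)
        differ = degenerate & (diff != 0)
        scores[equal_mean] = 0.0
        pvals[equal_mean] = 1.0
        finite = scores[np.isfinite(scores)]
        surrogate = (finite.max() if finite.size else 0.0) + 1.0
        scores[differ] = surrogate
        pvals[differ] = 0.0
    return SelectorScores(
        method="ttest",
        scores=scores,
        ranking=_rank_desc(scores),
        pvalues=pvals,
        meta={"equal_var": equal_var, "t": t},
    )


def _nipals_pls1(X: np.ndarray, y: np.ndarray, ncomp: int):
    """NIPALS PLS1 on centred X and autoscaled y; X-only deflation.

    Returns (W, ss) with W the p x A matrix of unit-norm weight vectors and
    ss the per-component explained y-variation q_a^2 * t_a't_a.
    """
    Xd = X - X.mean(axis=0)
    yc = y - y.mean()
    sd = yc.std()
    if sd == 0:
        raise ValueError("class labels are constant; PLS-DA undefined")
    yc = yc / sd
    p = X.shape[1]
    W = np.zeros((p, ncomp))
    ss = np.zeros(ncomp)
    done = 0
    for a in range(ncomp):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            break
        load = Xd.T @ t / tt
        q = (yc @ t) / tt
        W[:, a] = w
        ss[a] = q * q * tt
        Xd = Xd - np.outer(t, load)
        done = a + 1
    return W[:, :done], ss[:done]


def plsda_vip(data: LabeledMatrix, ncomp: int = 2) -> SelectorScores:
    """VIP scores from a PLS-DA model with ``ncomp`` components.

    VIP_j = sqrt(p * sum_a SS_a w_ja^2 / sum_a SS_a) with unit-norm weight
    vectors w_a and SS_a the y-variation explained by component a; by
    construction the mean squared VIP equals 1. If X cannot support the
    requested number of components the model is reduced with a warning.
    """
    _split_groups(data)  # validates group sizes
    max_comp = min(data.n - 1, data.p)
    if ncomp > max_comp:
        warnings.warn(
            f"reducing PLS components from {ncomp} to {max_comp} "
            f"(n={data.n}, p={data.p})",
            stacklevel=2,
        )
        ncomp = max_comp
    W, ss = _nipals_pls1(data.X, data.y.astype(float), ncomp)
    if W.shape[1] < ncomp:
        warnings.warn(
            f"PLS deflation exhausted after {W.shape[1]} component(s)",
            stacklevel=2,
        )
    if ss.sum() == 0:
        vip = np.zeros(data.p)
    else:
        vip = np.sqrt(data.p * (W**2 @ ss) / ss.sum())
    return SelectorScores(
        method="vip",
        scores=vip,
        ranking=_rank_desc(vip),
        meta={"ncomp": W.shape[1]},
    )


def _path_scores(
    data: LabeledMatrix,
    k_target: int,
    l1_ratio: float,
    method: str,
    n_alphas: int = 100,
    eps: float = 1e-3,
) -> SelectorScores:
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import enet_path, lasso_path

    if k_target < 1:
        raise ValueError(f"k_target must be >= 1, got {k_target}")
    # fortran order + explicit dtypes let the path solvers skip input
    # validation (check_input=False), which dominates at these sizes
    Xc = np.asfortranarray(data.X - data.X.mean(axis=0), dtype=np.float64)
    yc = np.ascontiguousarray(data.y - data.y.mean(), dtype=np.float64)
    p = data.p
    if not np.any(Xc):
        logger.warning("all-constant X: empty active set")
        return SelectorScores(
            method=method,
            scores=np.zeros(p),
            ranking=np.arange(p),
            meta={"lambda": np.nan, "active_size": 0, "l1_ratio": l1_ratio},
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if l1_ratio == 1.0:
            alphas, coefs, _ = lasso_path(
                Xc, yc, eps=eps, alphas=n_alphas, check_input=False
            )
        else:
            alphas, coefs, _ = enet_path(
                Xc, yc, l1_ratio=l1_ratio, eps=eps, alphas=n_alphas, check_input=False
            )
    active = coefs != 0.0  # (p, n_alphas), alphas descending
    sizes = active.sum(axis=0)
    ever = active.any(axis=1)
    first = np.where(ever, active.argmax(axis=1), len(alphas))
    reached = sizes >= k_target
    chosen = int(reached.argmax()) if reached.any() else int(sizes.argmax())
    coef_chosen = coefs[:, chosen]
    scores = np.where(ever, alphas[np.minimum(first, len(alphas) - 1)], 0.0)
    # entry order first, |coefficient| at the chosen lambda second, index last
    ranking = np.lexsort((np.arange(p), -np.abs(coef_chosen), first))
    return SelectorScores(
        method=method,
        scores=scores,
        ranking=ranking,
        meta={
            "lambda": float(alphas[chosen]),
            "active_size": int(sizes[chosen]),
            "l1_ratio": l1_ratio,
            "k_target": k_target,
            "path_sizes": sizes,
            "coef": coef_chosen,
        },
    )


def lasso_select(data: LabeledMatrix, k_target: int) -> SelectorScores:
    """LASSO path selector (mixing parameter alpha = 1).

    The path runs over 100 log-spaced lambdas from lambda_max (empty active
    set) down to 1e-3 * lambda_max. The operating lambda is the largest one
    whose active set holds at least ``k_target`` variables, or the lambda
    maximising the active-set size when the target is never reached.
    """
    return _path_scores(data, k_target, l1_ratio=1.0, method="lasso")


def enet_select(data: LabeledMatrix, k_target: int, alpha: float = 0.5) -> SelectorScores:
    """Elastic-net path selector at mixing parameter ``alpha`` (default 0.5).

    ``alpha=1`` reduces exactly to :func:`lasso_select`.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"mixing parameter must lie in (0, 1], got {alpha}")
    return _path_scores(data, k_target, l1_ratio=alpha, method="enet")


def get_selector(name: str):
    """Return ``f(data, k_target) -> SelectorScores`` for a method name."""
    if name == "ttest":
        return lambda data, k_target=None: ttest_scores(data)
    if name == "vip":
        return lambda data, k_target=None: plsda_vip(data)
    if name == "lasso":
        return lambda data, k_target: lasso_select(data, k_target)
    if name == "enet":
        return lambda data, k_target: enet_select(data, k_target)
    raise ValueError(f"unknown selector {name!r}; expected one of {METHOD_NAMES}")
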