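"""Synthetic two-group datasets for benchmarking variable selection.

Emulates autoscaled (log-transformed, centred, unit-variance) metabolomics
intensity matrices: variables are jointly standard multivariate normal in the
control group, and a chosen fraction of "significant" variables (true
biomarkers) receives a mean shift ``delta`` in the treatment group. Three
correlation structures are supported: independent, block (biomarkers
inter-correlated at 0.7, non-biomarkers at 0.1, zero between the two blocks)
and AR(1) with correlation ``rho**|i-j|``.

Also provides a spiked-in-serum-like fixture (two groups of 18 replicates,
60 metabolites, 8 true biomarkers with heterogeneous effect sizes) and the
published selection lists from the spiked-in worked example, so the whole
pipeline is exercisable without any external download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationSpec",
    "SimulationConfig",
    "LabeledMatrix",
    "build_correlation_matrix",
    "simulate_dataset",
    "spiked_fixture",
    "spiked_reference_example",
    "SPIKED_TRUE_NAMES",
]

STRUCTURES = ("independent", "block", "ar1")

#: eigenvalues above this (negative) tolerance are treated as zero when
#: factorising a correlation matrix for sampling
_PSD_TOL = 1e-10


def _round_half_even(x: float) -> int:
    """Round to nearest integer, halves to even (IEEE default)."""
    return int(np.rint(x))


@dataclass(frozen=True)
class CorrelationSpec:
    """Parameters of the inter-variable correlation structure.

    ``within_sig`` / ``within_nonsig`` / ``between_blocks`` apply to the
    block structure; ``rho`` applies to AR(1).
    """

    structure: str = "independent"
    rho: float = 0.5
    within_sig: float = 0.7
    within_nonsig: float = 0.1
    between_blocks: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"unknown correlation structure {self.structure!r}; "
                f"expected one of {STRUCTURES}"
            )
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        for name in ("within_sig", "within_nonsig", "between_blocks"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation benchmark.

    Parameters
    ----------
    n_total : even total sample size N (two equal groups of N/2).
    p : number of measured variables P.
    q : proportion of significant variables Q in (0, 1).
    delta : treatment-group mean shift on the autoscaled scale.
    correlation : CorrelationSpec.
    seed : RNG seed; generation is a pure function of (config, seed).
    shuffle_columns : apply a reproducible column permutation so that
        selectors cannot exploit the internal placement of the significant
        block at the leading indices.
    """

    n_total: int = 50
    p: int = 50
    q: float = 0.1
    delta: float = 0.4
    correlation: CorrelationSpec = field(default_factory=CorrelationSpec)
    seed: int = 0
    shuffle_columns: bool = True

    def __post_init__(self) -> None:
        if self.n_total <= 0 or self.n_total % 2 != 0:
            raise ValueError(f"n_total must be a positive even integer, got {self.n_total}")
        if self.p <= 0:
            raise ValueError(f"p must be positive, got {self.p}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")
        if self.delta < 0:
            raise ValueError(f"delta must be nonnegative, got {self.delta}")

    @property
    def n_significant(self) -> int:
        """k = round(P*Q), halves to even."""
        return _round_half_even(self.p * self.q)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class LabeledMatrix:
    """Samples-by-variables matrix with binary group labels.

    ``y`` codes control = 0, treatment = 1. ``truth`` is an optional boolean
    mask of the true biomarkers (available for simulated data).
    """

    X: np.ndarray
    y: np.ndarray
    var_names: np.ndarray
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.var_names = np.asarray(self.var_names, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError(f"y has length {self.y.shape}, expected ({n},)")
        if self.var_names.shape != (p,):
            raise ValueError(f"var_names has length {self.var_names.shape}, expected ({p},)")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("y must be coded 0 (control) / 1 (treatment)")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=bool)
            if self.truth.shape != (p,):
                raise ValueError("truth mask length must equal the number of variables")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def group_sizes(self) -> tuple[int, int]:
        return int(np.sum(self.y == 0)), int(np.sum(self.y == 1))

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "LabeledMatrix":
        """Row/column subset, keeping labels, names and truth aligned."""
        rows = np.arange(self.n) if rows is None else np.asarray(rows)
        cols = np.arange(self.p) if cols is None else np.asarray(cols)
        return LabeledMatrix(
            X=self.X[np.ix_(rows, cols)],
            y=self.y[rows],
            var_names=self.var_names[cols],
            truth=None if self.truth is None else self.truth[cols],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.var_names))
        df.insert(0, "group", self.y)
        df.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(self.n)])
        return df

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write as CSV (sample_id, group, variables); truth mask and nothing
        else goes to a ``<stem>.truth.json`` sidecar when present."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if sidecar and self.truth is not None:
            meta = {"truth": [str(v) for v in self.var_names[self.truth]]}
            path.with_suffix(".truth.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        if "group" not in df.columns:
            raise ValueError("CSV must contain a 'group' column coded 0/1")
        drop = [c for c in ("sample_id", "group") if c in df.columns]
        y = df["group"].to_numpy()
        X = df.drop(columns=drop)
        truth = None
        sidecar = path.with_suffix(".truth.json")
        if sidecar.exists():
            true_names = set(json.loads(sidecar.read_text())["truth"])
            truth = np.array([c in true_names for c in X.columns])
        return cls(X=X.to_numpy(), y=y, var_names=np.array(X.columns, dtype=object), truth=truth)


def build_correlation_matrix(spec: CorrelationSpec, p: int, k: int) -> np.ndarray:
    """Construct the P x P correlation matrix for a given structure.

    The k significant variables occupy the leading indices (internal
    convention; `simulate_dataset` optionally shuffles columns afterwards).

    Raises ``ValueError`` if the requested parameters yield a matrix that is
    not positive semi-definite.
    """
    if not 0 <= k <= p:
        raise ValueError(f"need 0 <= k <= p, got k={k}, p={p}")
    if spec.structure == "independent":
        return np.eye(p)
    if spec.structure == "ar1":
        idx = np.arange(p)
        sigma = spec.rho ** np.abs(idx[:, None] - idx[None, :])
    else:  # block
        sigma = np.full((p, p), spec.between_blocks)
        sigma[:k, :k] = spec.within_sig
        sigma[k:, k:] = spec.within_nonsig
        np.fill_diagonal(sigma, 1.0)
    w_min = float(np.linalg.eigvalsh(sigma)[0])
    if w_min < -_PSD_TOL:
        raise ValueError(
            "correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {w_min:.3e})"
        )
    return sigma


def _factor(sigma: np.ndarray) -> np.ndarray:
    """Symmetric factor L with L @ L.T = sigma (eigenvalues clipped at 0)."""
    w, v = np.linalg.eigh(sigma)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_dataset(config: SimulationConfig) -> LabeledMatrix:
    """Draw one two-group dataset from the model.

    Controls are mean-zero MVN with the configured correlation; the treatment
    group is identical except for a mean shift ``delta`` on the k = round(P*Q)
    significant variables. Fully reproducible from ``config.seed``.
    """
    p, n = config.p, config.n_total
    k = config.n_significant
    if k < 1:
        raise ValueError(
            f"round(p*q) = {k}: no significant variables to recover; "
            "increase p or q"
        )
    sigma = build_correlation_matrix(config.correlation, p, k)
    rng = np.random.default_rng(config.seed)
    if config.correlation.structure == "independent":
        X = rng.standard_normal((n, p))
    else:
        X = rng.standard_normal((n, p)) @ _factor(sigma).T
    n_half = n // 2
    y = np.repeat([0, 1], n_half)
    X[n_half:, :k] += config.delta
    truth = np.zeros(p, dtype=bool)
    truth[:k] = True
    names = np.array([f"V{i + 1:04d}" for i in range(p)], dtype=object)
    if config.shuffle_columns:
        perm = rng.permutation(p)
        X, truth, names = X[:, perm], truth[perm], names[perm]
    return LabeledMatrix(X=X, y=y, var_names=names, truth=truth)


# ---------------------------------------------------------------------------
# Spiked-in-serum-like fixture and the published worked example
# ---------------------------------------------------------------------------

SPIKED_TRUE_NAMES = ("Gly", "Ser", "Thr", "Asp", "Ala", "Val", "Lys", "Pyr")

# Treatment-group mean shifts (autoscaled units) for the 8 spiked metabolites.
# Magnitudes are heterogeneous, reflecting the unequal spiked concentration
# ranges; Pyr is deliberately near zero to emulate the pyroglutamic-acid
# signal that no method ever detected in the real experiment.
_SPIKED_SHIFTS = {
    "Gly": 1.6,
    "Ser": 1.2,
    "Thr": 1.0,
    "Asp": 0.6,
    "Ala": 1.4,
    "Val": 1.1,
    "Lys": 0.9,
    "Pyr": 0.05,
}

#: synthetic IDs for the 52 non-spiked metabolites, consistent with the
#: numeric labels appearing in the published selection lists
_SPIKED_NOISE_NAMES = tuple(f"M{i}" for i in range(10, 62))


def spiked_fixture(seed: int = 0) -> LabeledMatrix:
    """Synthetic stand-in for the spiked-in serum GC-MS dataset.

    36 samples (18 per group), 60 metabolites, 8 true biomarkers with
    heterogeneous group-mean shifts (see ``_SPIKED_SHIFTS``); the remaining
    52 metabolites are pure noise. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    names = np.array(list(SPIKED_TRUE_NAMES) + list(_SPIKED_NOISE_NAMES), dtype=object)
    p, n_half = len(names), 18
    X = rng.standard_normal((2 * n_half, p))
    shifts = np.array([_SPIKED_SHIFTS.get(v, 0.0) for v in names])
    X[n_half:] += shifts
    truth = np.array([v in SPIKED_TRUE_NAMES for v in names])
    y = np.repeat([0, 1], n_half)
    perm = rng.permutation(p)
    return LabeledMatrix(X=X[:, perm], y=y, var_names=names[perm], truth=truth[perm])


def spiked_reference_example() -> dict:
    """Published worked example from the spiked-in serum benchmark.

    Returns the selection lists reported for the six methods (stability-based
    VIP / t test / LASSO / elastic net at min_present = 0.5, and FDR-adjusted
    t test / VIP at adjusted p < 0.05), the 8 true spiked metabolites, and
    the full 60-metabolite universe. Non-spiked metabolites carry synthetic
    ``M<label>`` IDs matching the numeric labels of the published lists.
    """
    sel = {
        "stability_vip": [
            "Gly", "Ser", "Thr", "Ala", "Val", "Lys",
            "M20", "M36", "M24", "M13", "M42", "M23", "M41", "M44", "M57",
            "M19", "Asp",
        ],
        "stability_ttest": [
            "Gly", "Ser", "Thr", "Ala", "Val", "Lys",
            "M20", "M36", "M13", "M23", "M42", "M41", "Asp", "M44", "M57",
            "M24", "M48",
        ],
        "stability_lasso": ["Gly", "Ala", "Val", "M20", "M23", "Thr", "M21"],
        "stability_enet": ["Gly", "Ala", "Val", "M23", "M20", "Thr"],
        "fdr_ttest": ["Gly", "Ser", "Thr", "Ala", "Val", "Lys", "M25"],
        "fdr_vip": [],
    }
    return {
        "selections": sel,
        "truth_names": list(SPIKED_TRUE_NAMES),
        "var_names": list(SPIKED_TRUE_NAMES) + list(_SPIKED_NOISE_NAMES),
    }
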