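"""The multivariable epigenetic passage clock.

A passage clock is a linear predictor of passage number from beta values at a
small set of CpGs:

    predicted passage = intercept + sum_i coef_i * beta_i

The published four-CpG model (trained on pyrosequencing of MSCs, fibroblasts
and HUVECs) uses ALOX12 cg03762994, DOK6 cg25968937, LTC4S cg26683398 and
TNNI3K cg05264232.  Beta inputs are fractions in [0, 1]; pyrosequencing
percentages must be divided by 100 before scoring — the coefficient scale
(a unit swing of the TNNI3K beta moves the estimate by ~39 passages) makes
percentage inputs nonsense.

Predictions are not clipped: negative estimates are possible and reported
as-is.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet

__all__ = [
    "PassageModel",
    "CVReport",
    "published_model",
    "predict_passage",
    "train_model",
    "cross_validate",
    "evaluate_predictions",
    "r2_pearson",
    "r2_variance_explained",
]


@dataclass(frozen=True)
class PassageModel:
    """Linear passage predictor: intercept + per-CpG coefficients."""

    cpg_ids: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    provenance: str = ""

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        if coefs.shape != (len(self.cpg_ids),):
            raise ValueError("one coefficient per CpG required")
        if not (np.isfinite(coefs).all() and math.isfinite(self.intercept)):
            raise ValueError("model coefficients must be finite")

    def predict(self, betas) -> float | np.ndarray:
        """Evaluate the linear predictor on beta values (array-like, last axis = CpGs)."""
        arr = np.asarray(betas, dtype=float)
        return self.intercept + arr @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "cpg_ids": list(self.cpg_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "provenance": self.provenance,
        }

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PassageModel)
            and self.cpg_ids == other.cpg_ids
            and self.intercept == other.intercept
            and np.array_equal(self.coefficients, other.coefficients)
        )


#: Published four-CpG model: passage = 39.0341 - 10.9266*ALOX12 - 0.4219*DOK6
#: + 5.8979*LTC4S - 38.889*TNNI3K, betas as fractions in [0, 1].
_PUBLISHED = PassageModel(
    cpg_ids=("cg03762994", "cg25968937", "cg26683398", "cg05264232"),
    coefficients=np.array([-10.9266, -0.4219, 5.8979, -38.889]),
    intercept=39.0341,
    provenance=(
        "published four-CpG pyrosequencing passage predictor "
        "(ALOX12, DOK6, LTC4S, TNNI3K)"
    ),
)


def published_model() -> PassageModel:
    """The published four-CpG passage predictor with its printed coefficients."""
    return _PUBLISHED


def predict_passage(model: PassageModel, m: BetaMatrix) -> pd.Series:
    """Predict passage per sample; samples missing a model CpG become NaN.

    Unpredictable samples (a model CpG absent from the matrix or missing for
    that sample) are reported via a warning, never silently dropped.
    """
    absent = [c for c in model.cpg_ids if c not in m.values.index]
    if absent:
        raise KeyError(f"model CpG(s) not in matrix: {absent}")
    sub = m.values.loc[list(model.cpg_ids)]  # (n_cpgs, n_samples)
    pred = pd.Series(model.predict(sub.to_numpy().T), index=sub.columns, name="predicted_passage")
    bad = sub.isna().any(axis=0)
    if bad.any():
        pred[bad] = np.nan
        warnings.warn(
            f"sample(s) with missing model CpG betas are unpredictable: "
            f"{list(sub.columns[bad])}",
            stacklevel=2,
        )
    return pred


def _design(m: BetaMatrix, s: SampleSheet, cpg_ids: Sequence[str], target: str):
    samples = [sid for sid in m.sample_ids if sid in s.table.index]
    if len(samples) < len(m.sample_ids):
        missing = sorted(set(m.sample_ids) - set(samples))
        raise KeyError(f"sample(s) absent from sample sheet: {missing}")
    X = m.values.loc[list(cpg_ids), samples].to_numpy().T
    y = pd.to_numeric(s.table.loc[samples, target]).to_numpy(dtype=float)
    ok = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    return X[ok], y[ok], [sid for sid, good in zip(samples, ok) if good]


def _collinear_columns(X: np.ndarray, cpg_ids: Sequence[str]) -> list[str]:
    """Name the CpGs involved in rank deficiency via pivoted QR."""
    A = np.column_stack([np.ones(len(X)), X])
    from scipy.linalg import qr

    _, R, piv = qr(A, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    dropped = [int(p) for p, d in zip(piv, diag) if d <= tol]
    return [cpg_ids[p - 1] for p in dropped if p >= 1]


def train_model(
    m: BetaMatrix,
    s: SampleSheet,
    cpg_ids: Sequence[str],
    target: str = "passage",
    provenance: str = "trained",
) -> PassageModel:
    """OLS fit of the target (passage by default, cPD via ``target``) on betas."""
    cpg_ids = list(cpg_ids)
    X, y, _ = _design(m, s, cpg_ids, target)
    if len(y) < len(cpg_ids) + 2:
        raise ValueError(f"need at least {len(cpg_ids) + 2} samples, have {len(y)}")
    if np.ptp(y) == 0:
        raise ValueError(f"target {target!r} is constant; nothing to regress on")
    A = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise ValueError(f"rank-deficient design; collinear CpG(s): {_collinear_columns(X, cpg_ids)}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return PassageModel(
        cpg_ids=tuple(cpg_ids),
        coefficients=beta[1:],
        intercept=float(beta[0]),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# evaluation


def r2_pearson(pred: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation of predicted vs true values.

    This matches reporting R^2 from a predicted-vs-real scatter; it is
    insensitive to affine miscalibration.  Undefined (NaN) when either vector
    has zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.std(pred) == 0 or np.std(truth) == 0:
        return float("nan")
    return float(np.corrcoef(pred, truth)[0, 1] ** 2)


def r2_variance_explained(pred: np.ndarray, truth: np.ndarray) -> float:
    """1 - SSE/SST: penalizes miscalibration, can be negative."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    sst = float(((truth - truth.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    return 1.0 - float(((truth - pred) ** 2).sum()) / sst


def evaluate_predictions(pred, truth) -> tuple[float, float, float]:
    """(r2, rmse, mae) of predictions; r2 is squared Pearson correlation."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size < 2:
        raise ValueError("need >= 2 paired predictions")
    resid = pred - truth
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return r2_pearson(pred, truth), rmse, mae


@dataclass(frozen=True)
class CVReport:
    """Pooled held-out metrics from repeated k-fold cross-validation."""

    r2: float
    rmse: float
    mae: float
    folds: int
    repeats: int
    seed: int
    n: int
    r2_variance_explained: float
    predictions: pd.DataFrame = field(compare=False, repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "n": self.n,
            "r2_variance_explained": self.r2_variance_explained,
        }


def _fold_sizes(n: int, folds: int) -> list[int]:
    """Sizes as even as possible; the remainder goes to the first folds."""
    base, rem = divmod(n, folds)
    return [base + (1 if i < rem else 0) for i in range(folds)]


def cross_validate(
    m: BetaMatrix,
    s: SampleSheet,
    cpg_ids: Sequence[str],
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    target: str = "passage",
) -> CVReport:
    """Repeated k-fold cross-validation of a linear passage clock.

    Each repeat shuffles the samples with a seeded generator and splits them
    into ``folds`` contiguous blocks (as even as possible); every sample is
    scored once per repeat by a model trained on the other folds.  Metrics are
    pooled over all repeats' held-out predictions.  Deterministic for a given
    seed.
    """
    cpg_ids = list(cpg_ids)
    X, y, samples = _design(m, s, cpg_ids, target)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds usable samples n={n}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        start = 0
        for size in _fold_sizes(n, folds):
            test = perm[start : start + size]
            start += size
            if size == 0:
                continue
            train = np.setdiff1d(perm, test)
            A = np.column_stack([np.ones(len(train)), X[train]])
            beta, *_ = np.linalg.lstsq(A, y[train], rcond=None)
            pred = beta[0] + X[test] @ beta[1:]
            for i, p in zip(test, pred):
                rows.append((rep, samples[i], float(y[i]), float(p)))
    df = pd.DataFrame(rows, columns=["repeat", "sample_id", "true", "pred"])
    r2, rmse, mae = evaluate_predictions(df["pred"].to_numpy(), df["true"].to_numpy())
    return CVReport(
        r2=r2,
        rmse=rmse,
        mae=mae,
        folds=folds,
        repeats=repeats,
        seed=seed,
        n=n,
        r2_variance_explained=r2_variance_explained(
            df["pred"].to_numpy(), df["true"].to_numpy()
        ),
        predictions=df,
    )
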