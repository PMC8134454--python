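"""Signature trajectories across a reprogramming/differentiation time course.

During reprogramming of fibroblasts into iPSCs, culture-associated,
age-associated and pluripotency-associated methylation signatures are reset
around the same switch day.  This module quantifies that: the per-timepoint
mean absolute methylation difference to day 0 (per donor, then averaged),
the Pearson correlation between two signatures' trajectories, and per-sample
passage estimates as the mean of univariate per-CpG predictors
(passage = intercept_i + slope_i * beta_i, obtained by regressing passage on
beta for each CpG in a training cohort).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet

__all__ = [
    "SignatureSet",
    "signature_delta",
    "trajectory_correlation",
    "mean_univariate_passage",
    "fit_univariate_predictors",
    "read_signature",
    "write_signature",
]


@dataclass(frozen=True)
class SignatureSet:
    """A named CpG signature, optionally with per-CpG univariate predictors.

    ``predictors`` maps cpg_id -> (intercept, slope) such that
    intercept + slope * beta estimates passage from that CpG alone.
    """

    name: str
    cpg_ids: tuple[str, ...]
    predictors: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cpg_ids", tuple(self.cpg_ids))
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError(f"signature {self.name!r}: duplicate cpg_ids")
        if self.predictors is not None:
            for cpg, (a, b) in self.predictors.items():
                if not (np.isfinite(a) and np.isfinite(b)):
                    raise ValueError(f"non-finite predictor for {cpg}")


def signature_delta(m: BetaMatrix, s: SampleSheet, sig: SignatureSet) -> pd.Series:
    """Mean absolute methylation difference to day 0, per timepoint.

    For each donor the day-0 betas are the baseline (averaged if replicated);
    |beta(t) - beta(0)| is averaged over the signature's CpGs per donor, then
    over donors.  Day 0 is exactly 0 by construction.  Donors without a day-0
    sample raise.
    """
    tbl = s.table
    samples = [sid for sid in m.sample_ids if sid in tbl.index]
    days = pd.to_numeric(tbl.loc[samples, "timepoint_days"])
    if days.isna().any():
        bad = days.index[days.isna()].tolist()
        raise ValueError(f"sample(s) without timepoint_days: {bad}")
    donors = tbl.loc[samples, "donor"]
    missing_cpgs = [c for c in sig.cpg_ids if c not in m.values.index]
    if missing_cpgs:
        raise KeyError(f"signature CpG(s) not in matrix: {missing_cpgs[:10]}")
    B = m.values.loc[list(sig.cpg_ids), samples]

    no_day0 = sorted(set(donors) - set(donors[days == 0]))
    if no_day0:
        raise ValueError(f"donor(s) without a day-0 sample: {no_day0}")

    baselines = {
        d: B.loc[:, (donors == d) & (days == 0)].mean(axis=1) for d in donors.unique()
    }
    per_donor_day: dict[float, list[float]] = {}
    for sid in samples:
        d, t = donors[sid], float(days[sid])
        delta = float((B[sid] - baselines[d]).abs().mean())
        per_donor_day.setdefault(t, []).append(delta)
    out = pd.Series(
        {t: float(np.mean(v)) for t, v in sorted(per_donor_day.items())},
        name=sig.name,
    )
    out.index.name = "timepoint_days"
    return out


def trajectory_correlation(delta_a: pd.Series, delta_b: pd.Series) -> float:
    """Pearson r of two per-timepoint trajectories (aligned on timepoints)."""
    joint = pd.concat([delta_a, delta_b], axis=1, join="inner").dropna()
    if len(joint) < 3:
        raise ValueError("need >= 3 shared timepoints")
    a, b = joint.iloc[:, 0].to_numpy(float), joint.iloc[:, 1].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance in a trajectory; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def mean_univariate_passage(m: BetaMatrix, sig: SignatureSet) -> pd.Series:
    """Per-sample passage estimate: mean of the per-CpG univariate predictions.

    CpGs missing in a sample are skipped; samples with no observed signature
    CpG become NaN (flagged via warning).
    """
    if sig.predictors is None:
        raise ValueError(f"signature {sig.name!r} has no per-CpG predictors")
    cpgs = [c for c in sig.cpg_ids if c in m.values.index]
    unknown = [c for c in cpgs if c not in sig.predictors]
    if unknown:
        raise KeyError(f"no predictor for signature CpG(s): {unknown[:10]}")
    if not cpgs:
        raise KeyError("none of the signature CpGs are in the matrix")
    B = m.values.loc[cpgs]
    a = np.array([sig.predictors[c][0] for c in cpgs])
    b = np.array([sig.predictors[c][1] for c in cpgs])
    est = a[:, None] + b[:, None] * B.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = pd.Series(np.nanmean(est, axis=0), index=B.columns, name=f"{sig.name}_passage")
    if out.isna().any():
        warnings.warn(
            f"sample(s) with no observed signature CpG: {list(out.index[out.isna()])}",
            stacklevel=2,
        )
    return out


def fit_univariate_predictors(
    m: BetaMatrix, s: SampleSheet, cpg_ids: Sequence[str], name: str = "custom"
) -> SignatureSet:
    """Derive per-CpG univariate passage predictors from a training cohort.

    For each CpG, passage is regressed on beta (OLS); the resulting
    (intercept, slope) pairs form the signature's predictors.
    """
    samples = [sid for sid in m.sample_ids if sid in s.table.index]
    p = pd.to_numeric(s.table.loc[samples, "passage"]).to_numpy(float)
    predictors: dict[str, tuple[float, float]] = {}
    for cpg in cpg_ids:
        y = m.values.loc[cpg, samples].to_numpy(float)
        ok = ~(np.isnan(y) | np.isnan(p))
        if ok.sum() < 3 or np.ptp(y[ok]) == 0:
            raise ValueError(f"CpG {cpg}: cannot fit univariate predictor (degenerate betas)")
        slope, intercept = np.polyfit(y[ok], p[ok], 1)
        predictors[cpg] = (float(intercept), float(slope))
    return SignatureSet(name=name, cpg_ids=tuple(cpg_ids), predictors=predictors)


def read_signature(path: str | Path) -> SignatureSet:
    with open(path) as fh:
        d = json.load(fh)
    preds = d.get("predictors")
    if preds is not None:
        preds = {k: (float(v[0]), float(v[1])) for k, v in preds.items()}
    return SignatureSet(name=d["name"], cpg_ids=tuple(d["cpg_ids"]), predictors=preds)


def write_signature(sig: SignatureSet, path: str | Path) -> None:
    payload = {"name": sig.name, "cpg_ids": list(sig.cpg_ids)}
    if sig.predictors is not None:
        payload["predictors"] = {k: list(v) for k, v in sig.predictors.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
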