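"""Identification of culture-associated CpGs.

CpGs whose methylation drifts continuously with passage number are found by
Pearson correlation of beta values with passage (|r| above a cutoff), refined
by a regression-slope filter, ranked by |r|, and combined into a small
multivariable clock by exhaustive best-subset search (two hyper- plus two
hypomethylated CpGs by default).  Also houses the outlier test used to drop
aberrant profiles before selection and the BS-minus-OxBS estimate of
5-hydroxymethylation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clock import PassageModel
from .io import BetaMatrix, SampleSheet

__all__ = [
    "CpGStat",
    "CandidateSet",
    "correlate_cpgs",
    "stats_table",
    "filter_candidates",
    "best_subset_model",
    "detect_outlier_samples",
    "estimate_hydroxymethylation",
    "mean_hydroxymethylation",
]


@dataclass(frozen=True)
class CpGStat:
    """Per-CpG linear association of beta with passage number."""

    cpg_id: str
    pearson_r: float  # NaN when undefined (zero variance or n < 3)
    slope_m: float  # beta units per passage
    intercept: float  # beta units
    n: int
    direction: str  # 'hyper', 'hypo' or 'none'


@dataclass(frozen=True)
class CandidateSet:
    """Culture-associated candidate CpGs, ordered by |r| descending."""

    hyper: tuple[str, ...]
    hypo: tuple[str, ...]
    r_cut: float
    slope_cut: float | None = None
    top_n: int | None = None

    def __post_init__(self) -> None:
        if set(self.hyper) & set(self.hypo):
            raise ValueError("hyper and hypo candidate sets overlap")

    def to_dict(self) -> dict:
        return {
            "hyper": list(self.hyper),
            "hypo": list(self.hypo),
            "r_cut": self.r_cut,
            "slope_cut": self.slope_cut,
            "top_n": self.top_n,
        }


def correlate_cpgs(m: BetaMatrix, s: SampleSheet, target: str = "passage") -> list[CpGStat]:
    """Pearson r and OLS slope/intercept of beta vs passage, per CpG.

    CpGs observed in fewer than 3 samples or with zero beta variance get an
    undefined (NaN) r and direction 'none'; they are excluded downstream but
    reported here.  Raises if all passages are identical.
    """
    samples = [sid for sid in m.sample_ids if sid in s.table.index]
    if len(samples) < len(m.sample_ids):
        missing = sorted(set(m.sample_ids) - set(samples))
        raise KeyError(f"sample(s) absent from sample sheet: {missing}")
    p = pd.to_numeric(s.table.loc[samples, target]).to_numpy(dtype=float)
    if np.ptp(p[~np.isnan(p)]) == 0:
        raise ValueError(f"all {target} values identical; correlation undefined")
    B = m.values[samples].to_numpy(dtype=float)  # (n_cpgs, n_samples)
    stats: list[CpGStat] = []
    for i, cpg in enumerate(m.cpg_ids):
        row = B[i]
        ok = ~(np.isnan(row) | np.isnan(p))
        x, y = p[ok], row[ok]
        n = int(ok.sum())
        if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            stats.append(CpGStat(cpg, float("nan"), float("nan"), float("nan"), n, "none"))
            continue
        xm, ym = x - x.mean(), y - y.mean()
        sxx = float(xm @ xm)
        syy = float(ym @ ym)
        sxy = float(xm @ ym)
        r = sxy / np.sqrt(sxx * syy)
        slope = sxy / sxx
        intercept = float(y.mean() - slope * x.mean())
        direction = "hyper" if slope > 0 else ("hypo" if slope < 0 else "none")
        stats.append(CpGStat(cpg, float(r), float(slope), intercept, n, direction))
    return stats


def stats_table(stats: Iterable[CpGStat]) -> pd.DataFrame:
    """CpGStat list as a DataFrame (TSV-ready: cpg_id, r, slope, intercept, n, direction)."""
    return pd.DataFrame(
        [
            {
                "cpg_id": st.cpg_id,
                "r": st.pearson_r,
                "slope": st.slope_m,
                "intercept": st.intercept,
                "n": st.n,
                "direction": st.direction,
            }
            for st in stats
        ]
    ).set_index("cpg_id")


def filter_candidates(
    stats: Iterable[CpGStat],
    r_cut: float,
    slope_cut: float | None = None,
    top_n: int | None = None,
) -> CandidateSet:
    """Select candidate CpGs: r > r_cut (hyper) or r < -r_cut (hypo).

    With ``slope_cut`` additionally require |slope| > slope_cut; with
    ``top_n`` keep only the top_n per direction by |r|.  Undefined
    correlations are never selected.
    """
    if not (0 < r_cut < 1):
        raise ValueError(f"r_cut must be in (0, 1), got {r_cut}")
    usable = [st for st in stats if np.isfinite(st.pearson_r)]
    if slope_cut is not None:
        usable = [st for st in usable if abs(st.slope_m) > slope_cut]
    hyper = sorted(
        (st for st in usable if st.pearson_r > r_cut),
        key=lambda st: (-abs(st.pearson_r), st.cpg_id),
    )
    hypo = sorted(
        (st for st in usable if st.pearson_r < -r_cut),
        key=lambda st: (-abs(st.pearson_r), st.cpg_id),
    )
    if top_n is not None:
        hyper, hypo = hyper[:top_n], hypo[:top_n]
    return CandidateSet(
        hyper=tuple(st.cpg_id for st in hyper),
        hypo=tuple(st.cpg_id for st in hypo),
        r_cut=r_cut,
        slope_cut=slope_cut,
        top_n=top_n,
    )


def best_subset_model(
    m: BetaMatrix,
    s: SampleSheet,
    candidates: CandidateSet,
    n_hyper: int = 2,
    n_hypo: int = 2,
    target: str = "passage",
) -> PassageModel:
    """Exhaustive best-subset search for the multivariable passage clock.

    Every combination of ``n_hyper`` hypermethylated and ``n_hypo``
    hypomethylated candidates is fitted by OLS (passage on betas); the subset
    with minimal residual sum of squares wins, ties broken by lexicographic
    CpG-id order.  Singular designs (duplicated beta columns) are skipped with
    a warning.
    """
    if len(candidates.hyper) < n_hyper or len(candidates.hypo) < n_hypo:
        raise ValueError(
            f"need >= {n_hyper} hyper and >= {n_hypo} hypo candidates, have "
            f"{len(candidates.hyper)}/{len(candidates.hypo)}"
        )
    k = n_hyper + n_hypo
    samples = [sid for sid in m.sample_ids if sid in s.table.index]
    p = pd.to_numeric(s.table.loc[samples, target]).to_numpy(dtype=float)
    all_ids = sorted(set(candidates.hyper) | set(candidates.hypo))
    B = m.values.loc[all_ids, samples].to_numpy(dtype=float)
    ok = ~(np.isnan(B).any(axis=0) | np.isnan(p))
    B, p = B[:, ok], p[ok]
    n = len(p)
    if n < k + 2:
        raise ValueError(f"need >= {k + 2} complete samples, have {n}")
    col = {cpg: i for i, cpg in enumerate(all_ids)}

    best_rss = np.inf
    best_subset: tuple[str, ...] | None = None
    best_fit: np.ndarray | None = None
    ones = np.ones((n, 1))
    for hyp in itertools.combinations(sorted(candidates.hyper), n_hyper):
        for hypo in itertools.combinations(sorted(candidates.hypo), n_hypo):
            subset = tuple(sorted(hyp + hypo))
            X = B[[col[c] for c in subset]].T
            A = np.hstack([ones, X])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                warnings.warn(f"skipping singular subset {subset}", stacklevel=2)
                continue
            beta, *_ = np.linalg.lstsq(A, p, rcond=None)
            rss = float(((p - A @ beta) ** 2).sum())
            # strict < plus sorted iteration order = lexicographic tie-break
            if rss < best_rss - 1e-12 or (
                abs(rss - best_rss) <= 1e-12 and best_subset is not None and subset < best_subset
            ):
                best_rss, best_subset, best_fit = rss, subset, beta
    if best_subset is None:
        raise ValueError("all candidate subsets were singular")
    return PassageModel(
        cpg_ids=best_subset,
        coefficients=best_fit[1:],
        intercept=float(best_fit[0]),
        provenance=f"best {n_hyper}+{n_hypo} subset of "
        f"{len(candidates.hyper)} hyper / {len(candidates.hypo)} hypo candidates",
    )


def detect_outlier_samples(
    m: BetaMatrix,
    s: SampleSheet,
    model: PassageModel,
    alpha: float = 0.05,
    target: str = "passage",
) -> list[str]:
    """Bonferroni outlier test on the passage regression.

    Refits passage on the model's CpG betas and tests the externally
    studentized residual of every sample, Bonferroni-adjusted; returns the
    samples with adjusted p < alpha (the procedure of R's car::outlierTest).
    """
    import statsmodels.api as sm

    samples = [sid for sid in m.sample_ids if sid in s.table.index]
    X = m.values.loc[list(model.cpg_ids), samples].to_numpy(dtype=float).T
    y = pd.to_numeric(s.table.loc[samples, target]).to_numpy(dtype=float)
    ok = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    X, y = X[ok], y[ok]
    kept = [sid for sid, good in zip(samples, ok) if good]
    if len(y) < X.shape[1] + 3:
        raise ValueError(f"need >= {X.shape[1] + 3} samples for the outlier test, have {len(y)}")
    if alpha <= 0:
        return []
    res = sm.OLS(y, sm.add_constant(X)).fit()
    table = res.outlier_test(method="bonf")  # student_resid, unadj_p, bonf(p)
    flagged = np.asarray(table)[:, 2] < alpha
    return [kept[i] for i in np.flatnonzero(flagged)]


def estimate_hydroxymethylation(bs: BetaMatrix, oxbs: BetaMatrix) -> pd.DataFrame:
    """Per-CpG, per-sample 5hmC estimate: beta(BS) - beta(OxBS).

    Bisulfite alone reads 5mC+5hmC, oxidative bisulfite only 5mC, so the
    difference estimates 5hmC.  Values may be negative (measurement noise)
    and are reported as-is.  CpG and sample ids must match exactly.
    """
    for axis, a, b in (
        ("cpg_id", bs.cpg_ids, oxbs.cpg_ids),
        ("sample_id", bs.sample_ids, oxbs.sample_ids),
    ):
        diff = set(a) ^ set(b)
        if diff:
            raise ValueError(f"BS/OxBS {axis} mismatch: {sorted(diff)[:10]}")
    return bs.values - oxbs.values.loc[bs.cpg_ids, bs.sample_ids]


def mean_hydroxymethylation(hmc: pd.DataFrame, cpg_set: Sequence[str]) -> float:
    """Mean 5hmC estimate over a CpG set (all samples pooled, NaN-aware)."""
    sub = hmc.loc[list(cpg_set)]
    return float(np.nanmean(sub.to_numpy(dtype=float)))
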