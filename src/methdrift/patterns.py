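"""Pattern-spectrum analysis of bisulfite amplicon reads.

Deep amplicon sequencing of bisulfite-converted DNA yields, per read, the
binary sequel of methylated/unmethylated states across the amplicon's CpGs
(an epiallele).  This module quantifies the diversity of those patterns
(frequency spectra and their Shannon index), the correlation structure
between neighboring CpGs at single-read level — the discriminating signal
between targeted epigenetic writers (coherent blocks, high neighbor
correlation) and epigenetic drift (independent per-CpG changes, near-zero
neighbor correlation) — and implements the single-read passage predictor:
each read is assigned the passage number (integer grid, 0..50) that
maximizes its Bernoulli likelihood under per-CpG linear
methylation-vs-passage models, and a sample is scored by the mean over its
reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, ReadPatternSet, SampleSheet, pattern_to_string

__all__ = [
    "PatternSpectrum",
    "SingleReadModel",
    "ReadPredictions",
    "pattern_spectrum",
    "shannon_index",
    "neighbor_correlation",
    "methylated_fractions",
    "cpg_passage_correlation",
    "fit_single_read_model",
    "predict_read",
    "predict_reads",
    "predict_sample_from_reads",
]


@dataclass(frozen=True)
class PatternSpectrum:
    """Normalized frequency of each distinct complete pattern in a sample."""

    amplicon: str
    sample_id: str
    frequencies: dict[str, float]  # pattern string ('0'/'1') -> frequency
    total_reads: int
    n_excluded: int = 0  # reads with missing states, not part of the spectrum

    def __post_init__(self) -> None:
        freqs = np.array(list(self.frequencies.values()), dtype=float)
        if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("pattern frequencies must be >= 0 and sum to 1")

    def proportions(self) -> np.ndarray:
        return np.array(list(self.frequencies.values()), dtype=float)


def pattern_spectrum(rps: ReadPatternSet) -> PatternSpectrum:
    """Frequency of each distinct complete pattern (reads with missing states
    are excluded from the spectrum and counted)."""
    complete = rps.complete()
    total = complete.n_reads
    if total == 0:
        raise ValueError(
            f"no complete reads for {rps.sample_id}/{rps.amplicon.name}; "
            "cannot form a pattern spectrum"
        )
    freqs = {
        pattern_to_string(pat): int(cnt) / total
        for pat, cnt in zip(complete.patterns, complete.counts)
    }
    return PatternSpectrum(
        amplicon=rps.amplicon.name,
        sample_id=rps.sample_id,
        frequencies=freqs,
        total_reads=total,
        n_excluded=rps.n_reads - total,
    )


def shannon_index(spec) -> float:
    """Shannon diversity H' = -sum_i p_i ln p_i (nats), with 0 ln 0 := 0.

    Accepts a :class:`PatternSpectrum` or any array-like of proportions
    (e.g. clone/barcode frequencies).
    """
    if isinstance(spec, PatternSpectrum):
        p = spec.proportions()
    else:
        p = np.asarray(list(spec.values()) if isinstance(spec, Mapping) else spec, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be >= 0 and sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _pooled_complete(sets: Sequence[ReadPatternSet] | ReadPatternSet) -> np.ndarray:
    if isinstance(sets, ReadPatternSet):
        sets = [sets]
    mats = [rps.complete().expanded() for rps in sets]
    mats = [m for m in mats if m.size]
    if not mats:
        return np.zeros((0, sets[0].amplicon.n_cpgs if sets else 0), dtype=np.int8)
    return np.vstack(mats)


def neighbor_correlation(sets: Sequence[ReadPatternSet] | ReadPatternSet) -> pd.DataFrame:
    """CpG x CpG Pearson correlation of single-read binary states.

    Reads of all supplied sets (e.g. every sample of a donor) are pooled;
    only complete reads enter.  CpGs with zero variance across reads yield
    undefined (NaN) rows/columns, flagged via a warning.
    """
    X = _pooled_complete(sets).astype(float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 complete reads for neighbor correlation")
    sd = X.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        warnings.warn(
            f"CpG position(s) {flat.tolist()} have zero variance; correlations undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    C[flat, :] = np.nan
    C[:, flat] = np.nan
    idx = pd.RangeIndex(X.shape[1], name="cpg_index")
    return pd.DataFrame(C, index=idx, columns=idx)


def methylated_fractions(rps: ReadPatternSet) -> np.ndarray:
    """Per-CpG methylated fraction over non-missing read states."""
    X = rps.expanded()
    frac = np.full(X.shape[1], np.nan)
    for i in range(X.shape[1]):
        obs = X[:, i] != MISSING
        if obs.any():
            frac[i] = X[obs, i].mean()
    return frac


def cpg_passage_correlation(
    sets: Mapping[str, ReadPatternSet], s: SampleSheet
) -> pd.Series:
    """Per-CpG Pearson r of sample-level methylated fraction vs passage."""
    if len(sets) < 3:
        raise ValueError("need >= 3 samples")
    samples = list(sets)
    p = s.passages(samples).to_numpy(dtype=float)
    if np.ptp(p) == 0:
        raise ValueError("all passages identical; correlation undefined")
    F = np.vstack([methylated_fractions(sets[sid]) for sid in samples])  # (n_samples, n_cpgs)
    out = np.full(F.shape[1], np.nan)
    for i in range(F.shape[1]):
        y = F[:, i]
        ok = ~np.isnan(y)
        if ok.sum() >= 3 and np.ptp(y[ok]) > 0 and np.ptp(p[ok]) > 0:
            out[i] = np.corrcoef(p[ok], y[ok])[0, 1]
    return pd.Series(out, index=pd.RangeIndex(F.shape[1], name="cpg_index"), name="r")


@dataclass(frozen=True)
class SingleReadModel:
    """Per-CpG linear methylation-vs-passage models plus a passage grid.

    ``intercepts[i] + slopes[i] * p`` is the modeled methylation probability
    of CpG i at passage p, clipped to [clip_eps, 1 - clip_eps] before entering
    read likelihoods (the floor prevents a single state from annihilating the
    product).
    """

    intercepts: np.ndarray  # beta units
    slopes: np.ndarray  # beta units per passage
    passage_grid: np.ndarray  # ascending integers, default 0..50
    clip_eps: float = 0.001

    def __post_init__(self) -> None:
        object.__setattr__(self, "intercepts", np.asarray(self.intercepts, dtype=float))
        object.__setattr__(self, "slopes", np.asarray(self.slopes, dtype=float))
        object.__setattr__(self, "passage_grid", np.asarray(self.passage_grid))
        if self.intercepts.shape != self.slopes.shape:
            raise ValueError("intercepts and slopes must align")
        if not (0 < self.clip_eps < 0.5):
            raise ValueError("clip_eps must be in (0, 0.5)")
        g = self.passage_grid
        if g.size == 0 or (np.diff(g) <= 0).any():
            raise ValueError("passage_grid must be non-empty and strictly ascending")

    @property
    def n_cpgs(self) -> int:
        return self.intercepts.size

    def probabilities(self) -> np.ndarray:
        """Clipped methylation probability per (grid passage, CpG)."""
        p = self.intercepts[None, :] + np.outer(self.passage_grid, self.slopes)
        return np.clip(p, self.clip_eps, 1.0 - self.clip_eps)


def fit_single_read_model(
    sets: Mapping[str, ReadPatternSet],
    s: SampleSheet,
    max_passage: int = 50,
    clip_eps: float = 0.001,
) -> SingleReadModel:
    """Fit per-CpG OLS of methylated fraction vs passage from training samples.

    Needs >= 3 training samples spanning >= 2 distinct passages.
    """
    if len(sets) < 3:
        raise ValueError("need >= 3 training samples")
    samples = list(sets)
    p = s.passages(samples).to_numpy(dtype=float)
    if np.unique(p).size < 2:
        raise ValueError("training passages are degenerate (need >= 2 distinct)")
    F = np.vstack([methylated_fractions(sets[sid]) for sid in samples])
    n_cpgs = F.shape[1]
    a = np.zeros(n_cpgs)
    b = np.zeros(n_cpgs)
    for i in range(n_cpgs):
        y = F[:, i]
        ok = ~np.isnan(y)
        if ok.sum() < 2:
            raise ValueError(f"CpG {i}: fewer than 2 samples with observed fraction")
        slope, intercept = np.polyfit(p[ok], y[ok], 1)
        a[i], b[i] = intercept, slope
    return SingleReadModel(
        intercepts=a,
        slopes=b,
        passage_grid=np.arange(0, max_passage + 1),
        clip_eps=clip_eps,
    )


def _log_likelihoods(model: SingleReadModel, X: np.ndarray) -> np.ndarray:
    """Log-likelihood per (pattern row, grid passage); missing states skipped."""
    P = model.probabilities()  # (G, C)
    logp, log1p = np.log(P), np.log1p(-P)
    is1 = (X == 1).astype(float)  # (N, C)
    is0 = (X == 0).astype(float)
    return is1 @ logp.T + is0 @ log1p.T  # (N, G)


def predict_read(model: SingleReadModel, pattern: np.ndarray) -> tuple[int, np.ndarray]:
    """Most likely passage for one read plus its log-likelihood over the grid.

    Missing states are skipped in the Bernoulli product; ties go to the
    smallest grid passage (argmax of the first maximum).  A read with all
    states missing is undefined and raises.
    """
    x = np.asarray(pattern).reshape(1, -1)
    if x.shape[1] != model.n_cpgs:
        raise ValueError(f"pattern length {x.shape[1]} != model CpGs {model.n_cpgs}")
    if (x == MISSING).all():
        raise ValueError("all CpG states missing; read passage undefined")
    ll = _log_likelihoods(model, x)[0]
    best = int(model.passage_grid[int(np.argmax(ll))])
    return best, ll


@dataclass(frozen=True)
class ReadPredictions:
    """Per-read passage assignments for one sample (heatmap-ready)."""

    sample_id: str
    mean_passage: float
    best_passages: np.ndarray  # per distinct predictable pattern
    counts: np.ndarray
    log_likelihoods: np.ndarray  # (n_patterns, grid size)
    passage_grid: np.ndarray
    n_unpredictable: int = 0

    def passage_histogram(self) -> pd.Series:
        """Read counts per predicted passage over the grid."""
        hist = pd.Series(0, index=pd.Index(self.passage_grid, name="passage"))
        for bp, c in zip(self.best_passages, self.counts):
            hist.loc[bp] += int(c)
        return hist


def predict_reads(model: SingleReadModel, rps: ReadPatternSet) -> ReadPredictions:
    """Assign every read of a sample to its most likely passage."""
    ok = ~(rps.patterns == MISSING).all(axis=1)
    pats, counts = rps.patterns[ok], rps.counts[ok]
    if pats.shape[0] == 0:
        raise ValueError(f"no predictable reads in {rps.sample_id}/{rps.amplicon.name}")
    ll = _log_likelihoods(model, pats)
    best_idx = np.argmax(ll, axis=1)  # first max -> smallest passage on ties
    best = model.passage_grid[best_idx].astype(float)
    mean = float(np.average(best, weights=counts))
    return ReadPredictions(
        sample_id=rps.sample_id,
        mean_passage=mean,
        best_passages=best.astype(int),
        counts=counts.copy(),
        log_likelihoods=ll,
        passage_grid=model.passage_grid.copy(),
        n_unpredictable=int(rps.counts[~ok].sum()),
    )


def predict_sample_from_reads(model: SingleReadModel, rps: ReadPatternSet) -> float:
    """Sample-level passage estimate: mean of per-read most likely passages."""
    return predict_reads(model, rps).mean_passage
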