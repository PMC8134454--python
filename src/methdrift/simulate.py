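"""Seeded generators for every input the pipeline consumes.

The generators encode the data-generating assumptions the analysis is built
to discriminate:

* ``simulate_cohort`` — per-CpG linear methylation drift with passage plus
  Gaussian noise (array-style beta matrices).
* ``simulate_reads`` — single-molecule patterns under two contrasting
  models: *independent drift* (each CpG an independent Bernoulli whose
  probability drifts linearly with passage) vs *targeted writer* (a latent
  all-or-nothing block state per read, observed with a small flip error).
* ``simulate_clonal_culture`` — oligoclonal expansion with heritable
  patterns, per-passage epimutation and bottleneck resampling, plus
  RGB-style lentiviral barcodes.
* ``simulate_hairpin`` — strand pairs with UMIs, PCR duplication and UMI
  sequencing errors, for hemimethylation analysis.
* ``simulate_timecourse`` — reprogramming kinetics with a shared logistic
  switch day across signatures.

All generators are pure functions of a :class:`SimConfig`: a single root
seed spawns fixed per-component substreams, so each generator is
bit-reproducible and independent of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hairpin import HairpinRead, HairpinPanel, _top_sequence
from .io import AmpliconDef, BetaMatrix, ReadPatternSet, SampleSheet
from .reprogramming import SignatureSet

__all__ = [
    "SimConfig",
    "CohortSim",
    "ClonalCultureSim",
    "HairpinSim",
    "TimecourseSim",
    "simulate_cohort",
    "simulate_reads",
    "simulate_clonal_culture",
    "simulate_hairpin",
    "simulate_timecourse",
    "random_amplicon",
    "amplicon_drift_params",
    "reads_to_fastq",
    "DEFAULT_PANEL",
]

# fixed substream ids: one per generator component
_COHORT, _READS, _CLONAL, _HAIRPIN, _TIMECOURSE, _AMPLICON = range(6)

#: hairpin assay constants shared by simulator and parser
DEFAULT_PANEL = HairpinPanel(
    linker_left="GGTTGGAAGG", linker_right="CCTTCCAACC", umi_length=12
)


def _default_passages() -> tuple[int, ...]:
    # two donors sampled at every passage 1..12 (24 array samples)
    return tuple(range(1, 13)) * 2


@dataclass(frozen=True)
class SimConfig:
    """Parameters of all generators; defaults are the study conditions.

    Probabilities are in [0, 1]; slopes and noise in beta units per passage
    and beta units respectively.  Outputs are bit-reproducible per seed.
    """

    seed: int = 0
    # cohort (array-style beta matrices)
    n_cpgs: int = 200
    n_drift_hyper: int = 10
    n_drift_hypo: int = 10
    slope_range: tuple[float, float] = (0.02, 0.02)
    noise_sd: float = 0.01
    passages: tuple[int, ...] = field(default_factory=_default_passages)
    # amplicon reads
    reads_per_sample: int = 2000
    model: str = "independent_drift"  # or "targeted_writer"
    writer_error: float = 0.05
    # clonal culture
    n_clones: int = 100
    epimutation_rate: float = 0.01
    bottleneck_frac: float = 0.01
    population_size: int = 10_000
    # hairpin
    hemi_rate: float = 0.1
    umi_length: int = 12
    pcr_duplication_mean: float = 5.0
    umi_error_rate: float = 0.01
    # reprogramming time course
    switch_day: float = 17.5
    tau: float = 2.0
    timepoints: tuple[int, ...] = (0, 3, 7, 11, 15, 20, 28, 35, 42, 49)
    n_donors: int = 3

    def __post_init__(self) -> None:
        for name in ("noise_sd", "writer_error", "epimutation_rate",
                     "bottleneck_frac", "hemi_rate", "umi_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.model not in {"independent_drift", "targeted_writer"}:
            raise ValueError(f"unknown read model {self.model!r}")
        if any(p < 0 for p in self.passages):
            raise ValueError("passages must be >= 0")
        lo, hi = self.slope_range
        if lo > hi:
            raise ValueError("slope_range must be (low, high)")

    def rng(self, *key: int) -> np.random.Generator:
        """Seeded substream generator for one component (and optional subkeys)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=tuple(key)))


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


# ---------------------------------------------------------------------------
# cohort of array-style beta profiles


@dataclass(frozen=True)
class CohortSim:
    """A simulated culture-expansion cohort with its generative ground truth."""

    beta: BetaMatrix
    sheet: SampleSheet
    truth: pd.DataFrame  # per CpG: baseline, slope, direction


def simulate_cohort(cfg: SimConfig) -> CohortSim:
    """Beta matrix with linear per-CpG drift: beta = clip(b0 + m*passage + eps).

    The first ``n_drift_hyper`` CpGs gain methylation with passage, the next
    ``n_drift_hypo`` lose it (|m| drawn from ``slope_range``); the rest are
    stable (m = 0).  Baselines leave headroom so drift rarely clips.  Noise
    is iid Gaussian with sd ``noise_sd``.
    """
    rng = cfg.rng(_COHORT)
    n_drift = cfg.n_drift_hyper + cfg.n_drift_hypo
    if n_drift > cfg.n_cpgs:
        raise ValueError("more drifting CpGs than CpGs")
    passages = np.asarray(cfg.passages, dtype=float)
    n_samples = passages.size

    cpg_ids = [f"cg{i:06d}" for i in range(cfg.n_cpgs)]
    sample_ids = [f"s{j:03d}" for j in range(n_samples)]

    slopes = np.zeros(cfg.n_cpgs)
    lo, hi = cfg.slope_range
    slopes[: cfg.n_drift_hyper] = rng.uniform(lo, hi, cfg.n_drift_hyper)
    slopes[cfg.n_drift_hyper : n_drift] = -rng.uniform(lo, hi, cfg.n_drift_hypo)

    b0 = np.empty(cfg.n_cpgs)
    b0[: cfg.n_drift_hyper] = rng.uniform(0.10, 0.30, cfg.n_drift_hyper)
    b0[cfg.n_drift_hyper : n_drift] = rng.uniform(0.65, 0.90, cfg.n_drift_hypo)
    b0[n_drift:] = rng.uniform(0.05, 0.95, cfg.n_cpgs - n_drift)

    eps = rng.normal(0.0, cfg.noise_sd, (cfg.n_cpgs, n_samples)) if cfg.noise_sd > 0 else 0.0
    vals = np.clip(b0[:, None] + np.outer(slopes, passages) + eps, 0.0, 1.0)

    autosomes = [f"chr{1 + (i % 22)}" for i in range(cfg.n_cpgs)]
    beta = BetaMatrix(
        pd.DataFrame(vals, index=cpg_ids, columns=sample_ids),
        cpg_annotation=dict(zip(cpg_ids, autosomes)),
    )
    n_donors = 2 if n_samples % 2 == 0 else 1
    sheet = SampleSheet.from_records(
        {
            "sample_id": sid,
            "passage": int(cfg.passages[j]),
            "donor": f"D{1 + (j * n_donors) // n_samples}",
            "cell_type": "MSC",
            "timepoint_days": pd.NA,
            "group": "train",
        }
        for j, sid in enumerate(sample_ids)
    )
    direction = np.array(
        ["hyper"] * cfg.n_drift_hyper
        + ["hypo"] * cfg.n_drift_hypo
        + ["stable"] * (cfg.n_cpgs - n_drift)
    )
    truth = pd.DataFrame(
        {"baseline": b0, "slope": slopes, "direction": direction}, index=cpg_ids
    )
    truth.index.name = "cpg_id"
    return CohortSim(beta=beta, sheet=sheet, truth=truth)


# ---------------------------------------------------------------------------
# amplicons and single-molecule reads


def random_amplicon(
    name: str, n_cpgs: int, seed: int = 0, spacing: int = 18, primer_len: int = 20
) -> AmpliconDef:
    """A synthetic amplicon: random CpG-free backbone with CpGs planted at
    regular offsets, primer-sized flanks free of CpGs."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_AMPLICON, _crc(name))))
    first = primer_len + 5
    offsets = tuple(first + i * spacing for i in range(n_cpgs))
    length = offsets[-1] + spacing + primer_len if n_cpgs else 2 * primer_len + 10
    bases = rng.choice(list("ACGT"), size=length)
    seq = list("".join(bases))
    # remove accidental CpGs so the only dyads are the planted ones
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    for o in offsets:
        seq[o], seq[o + 1] = "C", "G"
    # re-scan: planting a G could have created a new CpG just before an offset
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in offsets:
            seq[i] = "A"
    ref = "".join(seq)
    return AmpliconDef(
        name=name,
        reference_seq=ref,
        forward_primer=ref[:primer_len],
        reverse_primer=ref[-primer_len:],
        cpg_offsets=offsets,
    )


def amplicon_drift_params(cfg: SimConfig, amp: AmpliconDef) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG (intercept, slope) of the methylation-vs-passage line for one
    amplicon; fixed per (seed, amplicon) so all passages share them.

    Each CpG drifts up or down with equal probability (|slope| from
    ``slope_range``); rising CpGs start low, falling CpGs start high, so the
    line stays inside [0, 1] over the passage grid.
    """
    rng = cfg.rng(_READS, _crc(amp.name))
    n = amp.n_cpgs
    lo, hi = cfg.slope_range
    sign = rng.choice([1.0, -1.0], size=n)
    b = sign * rng.uniform(lo, hi, n)
    a = np.where(sign > 0, rng.uniform(0.10, 0.30, n), rng.uniform(0.70, 0.90, n))
    return a, b


def _clip_prob(p: np.ndarray) -> np.ndarray:
    # mirror the single-read predictor's probability floor
    return np.clip(p, 0.001, 0.999)


def simulate_reads(
    cfg: SimConfig,
    amp: AmpliconDef,
    passage: int,
    sample_id: str | None = None,
) -> ReadPatternSet:
    """Single-molecule patterns for one sample at the given passage.

    independent_drift: x_i ~ Bernoulli(clip(a_i + b_i * passage)) per CpG,
    independently (epigenetic drift).  targeted_writer: a latent block state
    z ~ Bernoulli(q(passage)) per molecule, observed per CpG with flip
    probability ``writer_error`` (coherent modification by a targeted
    epigenetic writer).
    """
    sample_id = sample_id or f"{amp.name}_p{passage}"
    rng = cfg.rng(_READS, _crc(amp.name), int(passage), _crc(sample_id))
    n, c = cfg.reads_per_sample, amp.n_cpgs
    a, b = amplicon_drift_params(cfg, amp)
    if cfg.model == "independent_drift":
        probs = _clip_prob(a + b * passage)
        X = (rng.random((n, c)) < probs).astype(np.int8)
    else:
        q = float(_clip_prob(np.atleast_1d(np.mean(a) + np.mean(np.abs(b)) * passage))[0])
        z = (rng.random(n) < q).astype(np.int8)
        flips = (rng.random((n, c)) < cfg.writer_error).astype(np.int8)
        X = np.bitwise_xor(z[:, None], flips)
    return ReadPatternSet.from_reads(amp, sample_id, X)


def reads_to_fastq(rps: ReadPatternSet, path: str | Path) -> None:
    """Write a pattern set as bisulfite-converted FASTQ reads (Phred+33)."""
    amp = rps.amplicon
    with open(path, "w") as fh:
        k = 0
        for pat, cnt in zip(rps.patterns, rps.counts):
            seq = _top_sequence(amp, pat)
            for _ in range(int(cnt)):
                fh.write(f"@{rps.sample_id}_{k}\n{seq}\n+\n{'I' * len(seq)}\n")
                k += 1


# ---------------------------------------------------------------------------
# clonal culture with barcodes


@dataclass(frozen=True)
class ClonalCultureSim:
    """Oligoclonal culture: clone frequencies, barcodes, heritable patterns."""

    amplicon: AmpliconDef
    frequencies: pd.DataFrame  # recorded passage x clone_id, rows sum to 1
    barcodes: pd.DataFrame  # clone_id, barcode, rgb
    clone_patterns: dict[int, np.ndarray]  # passage -> (n_clones, n_cpgs) int8
    reads_per_sample: int

    def clone_read_sets(self, passage: int) -> dict[str, ReadPatternSet]:
        """Per-clone pattern sets at a recorded passage (counts ~ frequency)."""
        freqs = self.frequencies.loc[passage]
        pats = self.clone_patterns[passage]
        out: dict[str, ReadPatternSet] = {}
        for k, clone in enumerate(self.frequencies.columns):
            cnt = int(round(freqs.iloc[k] * self.reads_per_sample))
            if cnt > 0:
                out[clone] = ReadPatternSet(
                    self.amplicon, f"{clone}_p{passage}", pats[[k]], np.array([cnt])
                )
        return out

    def pooled_reads(self, passage: int, sample_id: str | None = None) -> ReadPatternSet:
        """All clones' reads pooled into one sample at a recorded passage."""
        sets = self.clone_read_sets(passage)
        mats = np.vstack([s.expanded() for s in sets.values()])
        return ReadPatternSet.from_reads(
            self.amplicon, sample_id or f"pool_p{passage}", mats
        )


def simulate_clonal_culture(cfg: SimConfig, amp: AmpliconDef) -> ClonalCultureSim:
    """Oligoclonal expansion with heritable patterns and RGB barcodes.

    ``n_clones`` founder clones carry a random heritable pattern over the
    amplicon's CpGs, a 16-nt lentiviral barcode and one of three fluorescent
    proteins.  Each passage the clone patterns epimutate (per-CpG flip
    probability ``epimutation_rate``) and the population passes a bottleneck:
    ``bottleneck_frac * population_size`` cells are drawn multinomially and
    regrown, so clone diversity drifts downward over passages.
    """
    rng = cfg.rng(_CLONAL, _crc(amp.name))
    recorded = sorted(set(int(p) for p in cfg.passages))
    max_p = recorded[-1]
    n, c = cfg.n_clones, amp.n_cpgs

    clones = [f"clone{k:03d}" for k in range(n)]
    barcodes = pd.DataFrame(
        {
            "clone_id": clones,
            "barcode": ["".join(rng.choice(list("ACGT"), 16)) for _ in range(n)],
            "rgb": rng.choice(["red", "green", "blue"], n),
        }
    ).set_index("clone_id")

    patterns = (rng.random((n, c)) < 0.3).astype(np.int8)
    counts = rng.multinomial(cfg.population_size, np.full(n, 1.0 / n)).astype(float)

    freq_rows: dict[int, np.ndarray] = {}
    pattern_snap: dict[int, np.ndarray] = {}
    bottleneck = max(1, int(round(cfg.bottleneck_frac * cfg.population_size)))
    for p in range(max_p + 1):
        if p > 0:
            if cfg.epimutation_rate > 0:
                flips = rng.random((n, c)) < cfg.epimutation_rate
                patterns = np.where(flips, 1 - patterns, patterns).astype(np.int8)
            freqs = counts / counts.sum()
            counts = rng.multinomial(bottleneck, freqs).astype(float)
            alive = counts > 0
            if not alive.any():  # pragma: no cover - bottleneck >= 1 guards this
                raise RuntimeError("population went extinct")
        if p in recorded:
            freq_rows[p] = counts / counts.sum()
            pattern_snap[p] = patterns.copy()

    frequencies = pd.DataFrame(
        np.vstack([freq_rows[p] for p in recorded]),
        index=pd.Index(recorded, name="passage"),
        columns=clones,
    )
    return ClonalCultureSim(
        amplicon=amp,
        frequencies=frequencies,
        barcodes=barcodes,
        clone_patterns=pattern_snap,
        reads_per_sample=cfg.reads_per_sample,
    )


# ---------------------------------------------------------------------------
# hairpin strand pairs


@dataclass(frozen=True)
class HairpinSim:
    """Simulated hairpin library: PCR-amplified reads plus the molecule truth."""

    reads: list[HairpinRead]  # post-PCR, with UMI errors
    molecules: list[HairpinRead]  # one per original molecule (truth)
    n_molecules: int


def simulate_hairpin(
    cfg: SimConfig, amp: AmpliconDef, passage: int, sample_id: str | None = None
) -> HairpinSim:
    """Strand pairs with UMIs, PCR duplication and UMI sequencing errors.

    Top-strand patterns follow the independent-drift read model; the bottom
    strand copies the top with per-CpG flip probability ``hemi_rate``.  Each
    molecule gets a distinct UMI (ideal molecular tagging) and
    ``1 + Poisson(pcr_duplication_mean - 1)`` PCR copies; each copy's UMI
    suffers per-base substitution errors at ``umi_error_rate``.
    """
    sample_id = sample_id or f"{amp.name}_hp_p{passage}"
    rng = cfg.rng(_HAIRPIN, _crc(amp.name), int(passage), _crc(sample_id))
    n, c = cfg.reads_per_sample, amp.n_cpgs
    a, b = amplicon_drift_params(cfg, amp)
    probs = _clip_prob(a + b * passage)
    top = (rng.random((n, c)) < probs).astype(np.int8)
    flips = (rng.random((n, c)) < cfg.hemi_rate).astype(np.int8)
    bottom = np.bitwise_xor(top, flips)

    umis = _distinct_umis(rng, n, cfg.umi_length)
    molecules = [
        HairpinRead(umi=umis[i], top_states=top[i], bottom_states=bottom[i])
        for i in range(n)
    ]
    lam = max(cfg.pcr_duplication_mean - 1.0, 0.0)
    copies = 1 + rng.poisson(lam, n)
    reads: list[HairpinRead] = []
    alphabet = np.array(list("ACGT"))
    for i in range(n):
        for _ in range(int(copies[i])):
            umi = umis[i]
            if cfg.umi_error_rate > 0:
                chars = np.array(list(umi))
                err = rng.random(cfg.umi_length) < cfg.umi_error_rate
                if err.any():
                    chars[err] = alphabet[rng.integers(0, 4, int(err.sum()))]
                    umi = "".join(chars)
            reads.append(HairpinRead(umi=umi, top_states=top[i], bottom_states=bottom[i]))
    perm = rng.permutation(len(reads))
    reads = [reads[j] for j in perm]
    return HairpinSim(reads=reads, molecules=molecules, n_molecules=n)


def _distinct_umis(rng: np.random.Generator, n: int, length: int) -> list[str]:
    if n > 4**length:
        raise ValueError("UMI space too small for distinct tagging")
    seen: set[str] = set()
    out: list[str] = []
    alphabet = list("ACGT")
    while len(out) < n:
        batch = rng.integers(0, 4, size=(n - len(out) + 8, length))
        for row in batch:
            u = "".join(alphabet[k] for k in row)
            if u not in seen:
                seen.add(u)
                out.append(u)
                if len(out) == n:
                    break
    return out


# ---------------------------------------------------------------------------
# reprogramming time course


@dataclass(frozen=True)
class TimecourseSim:
    """Reprogramming course: betas over days, sample sheet, signatures, truth."""

    beta: BetaMatrix
    sheet: SampleSheet
    signatures: dict[str, SignatureSet]
    truth: pd.DataFrame  # per CpG: signature, start, end


def simulate_timecourse(
    cfg: SimConfig,
    signatures: Sequence[tuple[str, int]] = (
        ("culture", 30),
        ("age", 20),
        ("pluripotency", 30),
    ),
) -> TimecourseSim:
    """Logistic switching of all signatures at a shared day.

    Per CpG, beta(t) = start + (end - start) * expit((t - switch_day) / tau)
    + noise; half of each signature's CpGs rise (low start, high end), half
    fall, mirroring re-methylation of culture-hypomethylated sites and reset
    of pluripotency/age signatures around the same day.
    """
    from scipy.special import expit

    rng = cfg.rng(_TIMECOURSE)
    days = np.asarray(cfg.timepoints, dtype=float)
    sig_sets: dict[str, SignatureSet] = {}
    rows = []
    cpg_ids: list[str] = []
    starts: list[float] = []
    ends: list[float] = []
    for name, n in signatures:
        ids = [f"{name}_cg{i:04d}" for i in range(n)]
        rising = np.arange(n) < n // 2
        start = np.where(rising, rng.uniform(0.05, 0.20, n), rng.uniform(0.70, 0.90, n))
        end = np.where(rising, rng.uniform(0.70, 0.90, n), rng.uniform(0.05, 0.20, n))
        sig_sets[name] = SignatureSet(name=name, cpg_ids=tuple(ids))
        cpg_ids.extend(ids)
        starts.extend(start)
        ends.extend(end)
        rows.extend({"signature": name, "start": s, "end": e} for s, e in zip(start, end))
    start_arr = np.array(starts)
    end_arr = np.array(ends)

    switch = expit((days - cfg.switch_day) / cfg.tau)  # (T,)
    sample_ids: list[str] = []
    records = []
    cols = []
    for d in range(1, cfg.n_donors + 1):
        for t, s in zip(days, switch):
            sid = f"D{d}_day{int(t):02d}"
            sample_ids.append(sid)
            records.append(
                {
                    "sample_id": sid,
                    "passage": 0,
                    "donor": f"D{d}",
                    "cell_type": "fibroblast",
                    "timepoint_days": int(t),
                    "group": "timecourse",
                }
            )
            col = start_arr + (end_arr - start_arr) * s
            cols.append(col)
    vals = np.column_stack(cols)
    if cfg.noise_sd > 0:
        vals = vals + rng.normal(0.0, cfg.noise_sd, vals.shape)
    beta = BetaMatrix(pd.DataFrame(np.clip(vals, 0, 1), index=cpg_ids, columns=sample_ids))
    truth = pd.DataFrame(rows, index=cpg_ids)
    truth.index.name = "cpg_id"
    return TimecourseSim(
        beta=beta,
        sheet=SampleSheet.from_records(records),
        signatures=sig_sets,
        truth=truth,
    )
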