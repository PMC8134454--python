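"""Readers, writers and preprocessing for methylation data.

On-disk formats
---------------
* beta matrix: TSV, header ``cpg_id<TAB>sample1<TAB>sample2...``, one row per
  CpG; cells are methylation fractions (beta values) in [0, 1]; missing values
  are written as ``.`` (empty cells are also accepted on input).
* sample sheet: CSV with columns
  ``sample_id,passage,donor,cell_type,timepoint_days,group``.
* amplicon panels: JSON (CpG offsets as integer arrays), optionally paired
  with a FASTA file holding the reference sequences.
* bisulfite amplicon reads: FASTQ (Phred+33).
* passage models: JSON.

All coordinates are 0-based, half-open; a CpG is identified by the offset of
its C on the reference (+) strand.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "AmpliconDef",
    "ReadPatternSet",
    "BetaMatrixFormatError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "filter_cpgs_by_chromosome",
    "knn_impute",
    "quantile_normalize",
    "call_read_patterns",
    "read_amplicon_panel",
    "write_amplicon_panel",
    "write_model",
    "read_model",
    "read_pattern_table",
    "write_pattern_table",
    "MISSING",
]

#: integer state code for a CpG whose methylation state could not be called
MISSING: int = -1


class BetaMatrixFormatError(ValueError):
    """A beta-matrix file violates the format contract (range, duplicates...)."""


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation fractions (beta values).

    ``values`` is a float DataFrame indexed by CpG id with one column per
    sample; missing entries are NaN.  ``cpg_annotation`` optionally maps CpG
    ids to chromosome labels (used for sex-chromosome filtering).
    """

    values: pd.DataFrame
    cpg_annotation: dict[str, str] | None = None

    def __post_init__(self) -> None:
        v = self.values
        v.index.name = "cpg_id"
        v.columns.name = None
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise BetaMatrixFormatError(f"duplicate cpg_id(s): {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise BetaMatrixFormatError(f"duplicate sample_id(s): {dups}")
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise BetaMatrixFormatError(
                f"beta value {arr[i, j]!r} outside [0,1] at cpg_id "
                f"{v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if not np.issubdtype(v.to_numpy().dtype, np.floating):
            self.values = v.astype(float)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def select_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        return replace(self, values=self.values.loc[list(cpg_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return replace(self, values=self.values[list(sample_ids)])


@dataclass
class SampleSheet:
    """Per-sample metadata: passage, donor, cell type, optional timepoint/group.

    Backed by a DataFrame indexed by sample_id.
    """

    table: pd.DataFrame

    COLUMNS = ("passage", "donor", "cell_type", "timepoint_days", "group")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id(s) in sample sheet: {dups}")
        for col in self.COLUMNS:
            if col not in t.columns:
                t[col] = pd.NA
        passages = pd.to_numeric(t["passage"], errors="raise")
        if (passages.dropna() < 0).any():
            bad = t.index[passages < 0].tolist()
            raise ValueError(f"negative passage for sample(s): {bad}")
        t["passage"] = passages

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def passages(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        s = self.table["passage"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "SampleSheet":
        df = pd.DataFrame(list(records)).set_index("sample_id")
        return cls(df)


@dataclass(frozen=True)
class AmpliconDef:
    """A bisulfite PCR amplicon: reference sequence, primers, CpG offsets.

    ``cpg_offsets`` are 0-based positions of the C of each CpG dyad on the
    reference (+) strand; they must point at ``CG`` dinucleotides.
    """

    name: str
    reference_seq: str
    forward_primer: str
    reverse_primer: str
    cpg_offsets: tuple[int, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        ref = self.reference_seq.upper()
        object.__setattr__(self, "reference_seq", ref)
        object.__setattr__(self, "forward_primer", self.forward_primer.upper())
        object.__setattr__(self, "reverse_primer", self.reverse_primer.upper())
        object.__setattr__(self, "cpg_offsets", tuple(int(o) for o in self.cpg_offsets))
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if set(ref) - set("ACGT"):
            raise ValueError(f"amplicon {self.name}: reference must be A/C/G/T only")
        offsets = self.cpg_offsets
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError(f"amplicon {self.name}: cpg_offsets must be strictly increasing")
        for o in offsets:
            if not (0 <= o < len(ref) - 1 and ref[o : o + 2] == "CG"):
                raise ValueError(
                    f"amplicon {self.name}: offset {o} does not point at a CpG "
                    f"(found {ref[o:o + 2]!r})"
                )
        if self.forward_primer not in ref:
            raise ValueError(f"amplicon {self.name}: forward primer not in reference")
        if self.reverse_primer not in ref:
            raise ValueError(f"amplicon {self.name}: reverse primer not in reference")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    def converted_reference(self) -> str:
        """Fully bisulfite-converted reference: every non-CpG C becomes T.

        CpG cytosines are left as C (their converted state depends on
        methylation and is called per read).
        """
        cpg = set(self.cpg_offsets)
        return "".join(
            "T" if (b == "C" and i not in cpg) else b
            for i, b in enumerate(self.reference_seq)
        )


@dataclass
class ReadPatternSet:
    """Per-read binary methylation patterns over one amplicon's CpGs.

    ``patterns`` has one row per *distinct* pattern (int8; 1 methylated,
    0 unmethylated, -1 missing) and ``counts`` the number of reads carrying
    each pattern.
    """

    amplicon: AmpliconDef
    sample_id: str
    patterns: np.ndarray
    counts: np.ndarray
    n_discarded: int = 0
    n_unanchored: int = 0

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.int8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.patterns.ndim != 2 or self.patterns.shape[1] != self.amplicon.n_cpgs:
            raise ValueError(
                f"patterns must be (n, {self.amplicon.n_cpgs}), got {self.patterns.shape}"
            )
        if self.counts.shape != (self.patterns.shape[0],):
            raise ValueError("counts must align with patterns")
        if (self.counts < 1).any():
            raise ValueError("read counts must be >= 1")
        if not np.isin(self.patterns, (-1, 0, 1)).all():
            raise ValueError("pattern states must be in {-1, 0, 1}")

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    def expanded(self) -> np.ndarray:
        """One row per read (duplicates expanded)."""
        return np.repeat(self.patterns, self.counts, axis=0)

    def complete(self) -> "ReadPatternSet":
        """Subset to reads with no missing states."""
        keep = (self.patterns != MISSING).all(axis=1)
        return replace(self, patterns=self.patterns[keep], counts=self.counts[keep])

    @staticmethod
    def from_reads(
        amplicon: AmpliconDef,
        sample_id: str,
        reads: np.ndarray,
        n_discarded: int = 0,
        n_unanchored: int = 0,
    ) -> "ReadPatternSet":
        """Build from a (n_reads, n_cpgs) per-read state array, deduplicating."""
        reads = np.asarray(reads, dtype=np.int8).reshape(-1, amplicon.n_cpgs)
        if reads.shape[0] == 0:
            pats, counts = reads, np.zeros(0, dtype=np.int64)
        else:
            pats, counts = np.unique(reads, axis=0, return_counts=True)
        return ReadPatternSet(amplicon, sample_id, pats, counts, n_discarded, n_unanchored)


# ---------------------------------------------------------------------------
# beta matrix TSV


def read_beta_matrix(
    path: str | Path, annotation: Mapping[str, str] | None = None
) -> BetaMatrix:
    """Read a beta-value matrix from TSV (first column ``cpg_id``).

    Empty cells and ``.`` become missing.  Values outside [0, 1] or duplicate
    CpG ids raise :class:`BetaMatrixFormatError` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."], keep_default_na=True)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise BetaMatrixFormatError(f"non-numeric cell in {path}: {exc}") from exc
    return BetaMatrix(df, cpg_annotation=dict(annotation) if annotation else None)


def write_beta_matrix(m: BetaMatrix, path: str | Path) -> None:
    """Write a beta matrix as TSV; missing values are written as ``.``."""
    out = m.values.copy()
    out.index.name = "cpg_id"
    out.to_csv(path, sep="\t", na_rep=".")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("sample sheet must have a 'sample_id' column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(s: SampleSheet, path: str | Path) -> None:
    out = s.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# preprocessing


def filter_cpgs_by_chromosome(m: BetaMatrix, excluded: Iterable[str]) -> BetaMatrix:
    """Drop CpGs annotated to the excluded chromosomes (e.g. {"chrX", "chrY"}).

    Every retained-or-judged CpG must be annotated; unannotated CpGs raise.
    Row order is otherwise preserved.
    """
    excluded = set(excluded)
    if not excluded:
        return m
    ann = m.cpg_annotation or {}
    missing = [c for c in m.cpg_ids if c not in ann]
    if missing:
        raise ValueError(f"no chromosome annotation for CpG(s): {missing[:10]}")
    keep = [c for c in m.cpg_ids if ann[c] not in excluded]
    return BetaMatrix(m.values.loc[keep], cpg_annotation=dict(m.cpg_annotation or {}))


def knn_impute(m: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Impute missing betas from the k nearest CpG rows.

    Distance between two CpG rows is plain Euclidean over the samples observed
    in *both* rows; for each missing cell the k nearest other rows observed at
    that sample contribute their value's mean (ties in distance broken by row
    order).  Imputed values are clipped to [0, 1]; observed cells are
    untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = m.values.to_numpy(dtype=float).copy()
    obs = ~np.isnan(vals)
    if obs.all():
        return m
    empty = ~obs.any(axis=1)
    if empty.any():
        bad = [m.cpg_ids[i] for i in np.flatnonzero(empty)]
        raise ValueError(f"CpG row(s) entirely missing, cannot impute: {bad[:10]}")
    n = vals.shape[0]
    out = vals.copy()
    for i in np.flatnonzero(~obs.all(axis=1)):
        shared = obs & obs[i]  # (n, p) columns observed in both rows
        diff = np.where(shared, vals - vals[i], 0.0)
        with np.errstate(invalid="ignore"):
            dist = np.sqrt(np.nansum(diff**2, axis=1))
        dist[~shared.any(axis=1)] = np.inf
        dist[i] = np.inf
        for j in np.flatnonzero(~obs[i]):
            donors = np.flatnonzero(obs[:, j] & np.isfinite(dist))
            if donors.size < k:
                raise ValueError(
                    f"fewer than k={k} complete neighbor rows for CpG "
                    f"{m.cpg_ids[i]!r} at sample {m.sample_ids[j]!r}"
                )
            # stable sort on distance -> ties broken by row order
            nearest = donors[np.argsort(dist[donors], kind="stable")[:k]]
            out[i, j] = float(np.clip(vals[nearest, j].mean(), 0.0, 1.0))
    return BetaMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        cpg_annotation=dict(m.cpg_annotation) if m.cpg_annotation else None,
    )


def quantile_normalize(m: BetaMatrix) -> BetaMatrix:
    """Classical quantile normalization across samples.

    Each sample's values are replaced by the mean across samples of the values
    at the same rank; tied values receive the mean of their tied ranks'
    reference values.  After normalization every column has the same sorted
    vector.  Requires a complete matrix (impute first).
    """
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("matrix has missing values; run knn_impute first")
    n, p = vals.shape
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(p):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = ref.copy()
        # average the reference over runs of tied values
        boundaries = np.flatnonzero(np.diff(sorted_col)) + 1
        start = 0
        for stop in list(boundaries) + [n]:
            if stop - start > 1:
                assigned[start:stop] = ref[start:stop].mean()
            start = stop
        out[order, j] = assigned
    return BetaMatrix(
        pd.DataFrame(np.clip(out, 0.0, 1.0), index=m.values.index, columns=m.values.columns),
        cpg_annotation=dict(m.cpg_annotation) if m.cpg_annotation else None,
    )


# ---------------------------------------------------------------------------
# primer-anchored bisulfite CpG calling


def _primer_matches(read: str, primer_conv: str, wildcard: set[int]) -> int:
    """First position in ``read`` where the converted primer matches; -1 if none.

    Positions in ``wildcard`` (CpG cytosines inside the primer) accept C or T.
    """
    L = len(primer_conv)
    for start in range(0, len(read) - L + 1):
        ok = True
        for t in range(L):
            b = read[start + t]
            if t in wildcard:
                if b not in ("C", "T"):
                    ok = False
                    break
            elif b != primer_conv[t]:
                ok = False
                break
        if ok:
            return start
    return -1


def call_read_patterns(
    reads: str | Path | Iterable,
    amp: AmpliconDef,
    sample_id: str = "sample",
    max_mismatch_frac: float = 0.1,
) -> ReadPatternSet:
    """Call per-read CpG methylation states from bisulfite amplicon reads.

    Each read is anchored by an exact match of the bisulfite-converted forward
    primer (CpG positions inside the primer accept C or T).  At each CpG
    offset, C calls methylated, T unmethylated, anything else missing.  Reads
    whose non-CpG cytosine positions disagree with the fully converted
    reference in more than ``max_mismatch_frac`` of covered positions are
    discarded (incomplete bisulfite conversion or wrong locus); the discarded
    and unanchored counts are kept on the returned set.

    ``reads`` may be a FASTQ path or an iterable of Bio.SeqRecord / str.
    """
    if isinstance(reads, (str, Path)):
        records: Iterable = SeqIO.parse(str(reads), "fastq")
    else:
        records = reads

    ref = amp.reference_seq
    conv_ref = amp.converted_reference()
    primer_start = ref.index(amp.forward_primer)
    primer_conv = conv_ref[primer_start : primer_start + len(amp.forward_primer)]
    wildcard = {
        o - primer_start
        for o in amp.cpg_offsets
        if primer_start <= o < primer_start + len(amp.forward_primer)
    }
    noncpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in set(amp.cpg_offsets)]

    called: list[np.ndarray] = []
    n_total = n_unanchored = n_discarded = 0
    for rec in records:
        seq = str(getattr(rec, "seq", rec)).upper()
        n_total += 1
        a = _primer_matches(seq, primer_conv, wildcard)
        if a < 0:
            n_unanchored += 1
            continue
        shift = a - primer_start  # read position of reference offset o is o + shift
        covered = [i for i in noncpg_c if 0 <= i + shift < len(seq)]
        if covered:
            mism = sum(1 for i in covered if seq[i + shift] != "T")
            if mism / len(covered) > max_mismatch_frac:
                n_discarded += 1
                continue
        states = np.full(amp.n_cpgs, MISSING, dtype=np.int8)
        for idx, o in enumerate(amp.cpg_offsets):
            pos = o + shift
            if 0 <= pos < len(seq):
                b = seq[pos]
                states[idx] = 1 if b == "C" else (0 if b == "T" else MISSING)
        called.append(states)

    if n_total and (n_total - n_unanchored) / n_total < 0.01:
        raise ValueError(
            f"forward primer of amplicon {amp.name!r} not found in >=99% of reads "
            f"({n_unanchored}/{n_total} unanchored) — wrong amplicon?"
        )
    arr = np.vstack(called) if called else np.zeros((0, amp.n_cpgs), dtype=np.int8)
    return ReadPatternSet.from_reads(
        amp, sample_id, arr, n_discarded=n_discarded, n_unanchored=n_unanchored
    )


# ---------------------------------------------------------------------------
# amplicon panel JSON / FASTA


def read_amplicon_panel(
    json_path: str | Path, fasta_path: str | Path | None = None
) -> dict[str, AmpliconDef]:
    """Load amplicon definitions from a JSON panel.

    Each entry needs ``name``, ``forward_primer``, ``reverse_primer``,
    ``cpg_offsets`` and either an inline ``reference_seq`` or a sequence of
    the same name in ``fasta_path``.
    """
    with open(json_path) as fh:
        entries = json.load(fh)
    seqs: dict[str, str] = {}
    if fasta_path is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    panel: dict[str, AmpliconDef] = {}
    for e in entries:
        ref = e.get("reference_seq") or seqs.get(e["name"])
        if ref is None:
            raise ValueError(f"no reference sequence for amplicon {e['name']!r}")
        panel[e["name"]] = AmpliconDef(
            name=e["name"],
            reference_seq=ref,
            forward_primer=e["forward_primer"],
            reverse_primer=e["reverse_primer"],
            cpg_offsets=tuple(e["cpg_offsets"]),
            strand=e.get("strand", "+"),
        )
    return panel


def write_amplicon_panel(panel: Mapping[str, AmpliconDef], json_path: str | Path) -> None:
    entries = [
        {
            "name": a.name,
            "reference_seq": a.reference_seq,
            "forward_primer": a.forward_primer,
            "reverse_primer": a.reverse_primer,
            "cpg_offsets": list(a.cpg_offsets),
            "strand": a.strand,
        }
        for a in panel.values()
    ]
    with open(json_path, "w") as fh:
        json.dump(entries, fh, indent=1)


# ---------------------------------------------------------------------------
# model JSON

_MODEL_FIELDS = {"cpg_ids", "coefficients", "intercept", "provenance"}


def write_model(model, path: str | Path) -> None:
    """Serialize a PassageModel to JSON (lossless round trip)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_model(path: str | Path):
    """Read a PassageModel from JSON; unknown fields are ignored with a warning."""
    from .clock import PassageModel

    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed model file {path}: {exc}") from exc
    unknown = set(payload) - _MODEL_FIELDS
    if unknown:
        warnings.warn(f"ignoring unknown model field(s): {sorted(unknown)}", stacklevel=2)
    try:
        return PassageModel(
            cpg_ids=tuple(payload["cpg_ids"]),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            provenance=str(payload.get("provenance", "")),
        )
    except KeyError as exc:
        raise ValueError(f"malformed model file {path}: missing field {exc}") from exc


# ---------------------------------------------------------------------------
# pattern tables (TSV exchange format for ReadPatternSets)


def pattern_to_string(states: np.ndarray) -> str:
    """Encode an int8 state vector as '0'/'1'/'.' characters."""
    return "".join("." if s == MISSING else str(int(s)) for s in states)


def string_to_pattern(text: str) -> np.ndarray:
    return np.array([MISSING if c == "." else int(c) for c in text], dtype=np.int8)


def write_pattern_table(sets: Iterable[ReadPatternSet], path: str | Path) -> None:
    """Write pattern sets as TSV: sample_id, amplicon, pattern (0/1/.), count."""
    rows = []
    for rps in sets:
        for pat, cnt in zip(rps.patterns, rps.counts):
            rows.append(
                {
                    "sample_id": rps.sample_id,
                    "amplicon": rps.amplicon.name,
                    "pattern": pattern_to_string(pat),
                    "count": int(cnt),
                }
            )
    pd.DataFrame(rows, columns=["sample_id", "amplicon", "pattern", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_pattern_table(
    path: str | Path, panel: Mapping[str, AmpliconDef]
) -> list[ReadPatternSet]:
    """Read a pattern TSV back into one ReadPatternSet per (sample, amplicon)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "pattern": str})
    out: list[ReadPatternSet] = []
    for (sample, amp_name), grp in df.groupby(["sample_id", "amplicon"], sort=False):
        amp = panel[amp_name]
        pats = np.vstack([string_to_pattern(p) for p in grp["pattern"]])
        out.append(ReadPatternSet(amp, sample, pats, grp["count"].to_numpy()))
    return out
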