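"""Hairpin-bisulfite analysis: UMI clustering, dedup, hemimethylation rates.

Hairpin ligation covalently joins the two complementary strands of one DNA
molecule, so a single read reports the methylation state of a CpG dyad on
*both* strands; a unique molecular identifier (UMI) in the hairpin loop
distinguishes original molecules from PCR duplicates.  After directional UMI
clustering and per-cluster consensus, discordant dyads (methylated on only
one strand) give per-CpG hemimethylation rates.

Read layout expected by the parser (all bisulfite-converted, 5'->3'):

    [top strand][linker_left][UMI][linker_right][bottom strand]

where the bottom-strand segment is the converted reverse complement of the
reference; the bottom-strand C of the dyad at top offset ``o`` sits at index
``L - 2 - o`` of that segment (L = reference length).  Coordinates are always
reported on the top strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, AmpliconDef

__all__ = [
    "HairpinRead",
    "HairpinPanel",
    "UmiCluster",
    "cluster_umis",
    "dedupe_by_umi",
    "hemimethylation_rates",
    "parse_hairpin_fastq",
    "hairpin_reads_to_fastq",
    "read_hairpin_panel",
    "write_hairpin_panel",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class HairpinRead:
    """UMI-labeled top/bottom-strand CpG state vectors of one molecule."""

    umi: str
    top_states: np.ndarray
    bottom_states: np.ndarray

    def __post_init__(self) -> None:
        self.top_states = np.asarray(self.top_states, dtype=np.int8)
        self.bottom_states = np.asarray(self.bottom_states, dtype=np.int8)
        if self.top_states.shape != self.bottom_states.shape:
            raise ValueError("top and bottom state vectors must have equal length")


@dataclass(frozen=True)
class HairpinPanel:
    """Hairpin assay constants: linker arms flanking the UMI, UMI length."""

    linker_left: str
    linker_right: str
    umi_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "linker_left", self.linker_left.upper())
        object.__setattr__(self, "linker_right", self.linker_right.upper())
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")


@dataclass(frozen=True)
class UmiCluster:
    root: str
    members: tuple[str, ...]
    total_count: int


def _neighbor_index(umis: Sequence[str], length: int) -> dict[tuple[int, str], list[int]]:
    """Bucket UMIs by each single-position-masked key (O(n*L) adjacency)."""
    buckets: dict[tuple[int, str], list[int]] = defaultdict(list)
    for i, u in enumerate(umis):
        for pos in range(length):
            buckets[(pos, u[:pos] + u[pos + 1 :])].append(i)
    return buckets


def cluster_umis(
    umi_counts: Mapping[str, int], max_mismatch: int = 1
) -> list[UmiCluster]:
    """Directional adjacency clustering of UMIs.

    A directed edge u -> v exists when Hamming(u, v) <= max_mismatch and
    count(u) >= 2*count(v) - 1; clusters are the sets reachable from
    count-descending roots (each UMI joins at most one cluster).  The result
    is invariant to input ordering (nodes are processed by descending count,
    ties by UMI string).
    """
    if not umi_counts:
        return []
    umis = list(umi_counts)
    lengths = {len(u) for u in umis}
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths: {sorted(lengths)}")
    L = lengths.pop()

    if max_mismatch == 0:
        return [
            UmiCluster(u, (u,), int(umi_counts[u]))
            for u in sorted(umis, key=lambda u: (-umi_counts[u], u))
        ]
    if max_mismatch != 1:
        raise ValueError("only max_mismatch in {0, 1} is supported")

    order = sorted(range(len(umis)), key=lambda i: (-umi_counts[umis[i]], umis[i]))
    buckets = _neighbor_index(umis, L)
    counts = np.array([umi_counts[u] for u in umis], dtype=np.int64)
    assigned = np.full(len(umis), -1, dtype=np.int64)
    clusters: list[UmiCluster] = []
    for root in order:
        if assigned[root] >= 0:
            continue
        cid = len(clusters)
        stack = [root]
        assigned[root] = cid
        members = [root]
        while stack:
            u = stack.pop()
            seen: set[int] = set()
            for pos in range(L):
                key = (pos, umis[u][:pos] + umis[u][pos + 1 :])
                for v in buckets.get(key, ()):
                    if v == u or assigned[v] >= 0 or v in seen:
                        continue
                    seen.add(v)
                    if counts[u] >= 2 * counts[v] - 1:
                        assigned[v] = cid
                        members.append(v)
                        stack.append(v)
        clusters.append(
            UmiCluster(
                root=umis[root],
                members=tuple(sorted(umis[i] for i in members)),
                total_count=int(counts[members].sum()),
            )
        )
    return clusters


def dedupe_by_umi(
    reads: Iterable[HairpinRead], clusters: Sequence[UmiCluster]
) -> list[HairpinRead]:
    """Collapse PCR duplicates: one consensus read per UMI cluster.

    Per CpG and strand the majority non-missing state wins; ties (including
    all-missing) become missing.  Output order follows the cluster list.
    """
    by_umi: dict[str, list[HairpinRead]] = defaultdict(list)
    for r in reads:
        by_umi[r.umi].append(r)
    out: list[HairpinRead] = []
    for cl in clusters:
        group = [r for u in cl.members for r in by_umi.get(u, [])]
        if not group:
            continue
        top = np.stack([r.top_states for r in group])
        bot = np.stack([r.bottom_states for r in group])
        out.append(
            HairpinRead(
                umi=cl.root,
                top_states=_majority(top),
                bottom_states=_majority(bot),
            )
        )
    return out


def _majority(states: np.ndarray) -> np.ndarray:
    """Column-wise majority over {0,1}, ignoring missing; ties -> missing."""
    n1 = (states == 1).sum(axis=0)
    n0 = (states == 0).sum(axis=0)
    out = np.full(states.shape[1], MISSING, dtype=np.int8)
    out[n1 > n0] = 1
    out[n0 > n1] = 0
    return out


def hemimethylation_rates(reads: Sequence[HairpinRead]) -> pd.DataFrame:
    """Per-CpG strand-concordance counts and hemimethylation rate.

    For every CpG dyad with both strands called, counts concordant
    methylated (m,m), concordant unmethylated (u,u) and discordant pairs;
    rate = discordant / informative.  CpGs with zero informative pairs get a
    NaN rate (flagged in the ``informative`` column).
    """
    if not reads:
        raise ValueError("no hairpin reads")
    top = np.stack([r.top_states for r in reads])
    bot = np.stack([r.bottom_states for r in reads])
    informative = (top != MISSING) & (bot != MISSING)
    n_mm = ((top == 1) & (bot == 1) & informative).sum(axis=0)
    n_uu = ((top == 0) & (bot == 0) & informative).sum(axis=0)
    n_disc = (informative & (top != bot)).sum(axis=0)
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_inf > 0, n_disc / np.maximum(n_inf, 1), np.nan)
    return pd.DataFrame(
        {
            "n_mm": n_mm,
            "n_uu": n_uu,
            "n_discordant": n_disc,
            "informative": n_inf,
            "rate": rate,
        },
        index=pd.RangeIndex(top.shape[1], name="cpg_index"),
    )


# ---------------------------------------------------------------------------
# hairpin FASTQ serialization (synthetic read layout described in module docs)


def _top_sequence(amp: AmpliconDef, states: np.ndarray) -> str:
    seq = list(amp.converted_reference())
    for i, o in enumerate(amp.cpg_offsets):
        seq[o] = "C" if states[i] == 1 else ("T" if states[i] == 0 else "N")
    return "".join(seq)


def _bottom_sequence(amp: AmpliconDef, states: np.ndarray) -> str:
    """Converted bottom strand 5'->3' (reverse complement of the reference,
    with its own Cs converted except methylated CpG Cs)."""
    L = len(amp.reference_seq)
    bottom = list(_revcomp(amp.reference_seq))
    cpg_bottom_idx = {L - 2 - o: i for i, o in enumerate(amp.cpg_offsets)}
    for j, b in enumerate(bottom):
        if b != "C":
            continue
        i = cpg_bottom_idx.get(j)
        if i is None:
            bottom[j] = "T"
        else:
            s = states[i]
            bottom[j] = "C" if s == 1 else ("T" if s == 0 else "N")
    return "".join(bottom)


def hairpin_reads_to_fastq(
    reads: Iterable[HairpinRead], amp: AmpliconDef, panel: HairpinPanel, path: str | Path
) -> None:
    """Write hairpin reads as FASTQ (Phred+33, uniform quality)."""
    with open(path, "w") as fh:
        for k, r in enumerate(reads):
            seq = (
                _top_sequence(amp, r.top_states)
                + panel.linker_left
                + r.umi
                + panel.linker_right
                + _bottom_sequence(amp, r.bottom_states)
            )
            fh.write(f"@hp_{k}\n{seq}\n+\n{'I' * len(seq)}\n")


def parse_hairpin_fastq(
    reads: str | Path | Iterable,
    amp: AmpliconDef,
    panel: HairpinPanel,
) -> tuple[list[HairpinRead], int]:
    """Parse hairpin FASTQ into per-strand CpG state vectors.

    Reads lacking the linker (or a complete UMI) are discarded; the second
    element of the result is the discarded count.
    """
    from Bio import SeqIO

    if isinstance(reads, (str, Path)):
        records: Iterable = SeqIO.parse(str(reads), "fastq")
    else:
        records = reads
    L = len(amp.reference_seq)
    out: list[HairpinRead] = []
    n_discarded = 0
    for rec in records:
        seq = str(getattr(rec, "seq", rec)).upper()
        i = seq.find(panel.linker_left)
        if i < 0:
            n_discarded += 1
            continue
        umi_start = i + len(panel.linker_left)
        umi = seq[umi_start : umi_start + panel.umi_length]
        rest = seq[umi_start + panel.umi_length :]
        if len(umi) < panel.umi_length or not rest.startswith(panel.linker_right):
            n_discarded += 1
            continue
        top_seq = seq[:i]
        bottom_seq = rest[len(panel.linker_right) :]
        top = _call_states(top_seq, amp.cpg_offsets)
        bottom = _call_states(bottom_seq, tuple(L - 2 - o for o in amp.cpg_offsets))
        out.append(HairpinRead(umi=umi, top_states=top, bottom_states=bottom))
    return out, n_discarded


def _call_states(seq: str, offsets: Sequence[int]) -> np.ndarray:
    states = np.full(len(offsets), MISSING, dtype=np.int8)
    for i, o in enumerate(offsets):
        if 0 <= o < len(seq):
            b = seq[o]
            states[i] = 1 if b == "C" else (0 if b == "T" else MISSING)
    return states


def read_hairpin_panel(path: str | Path) -> HairpinPanel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return HairpinPanel(
        linker_left=d["linker_left"],
        linker_right=d["linker_right"],
        umi_length=int(d["umi_length"]),
    )


def write_hairpin_panel(panel: HairpinPanel, path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "linker_left": panel.linker_left,
                "linker_right": panel.linker_right,
                "umi_length": panel.umi_length,
            },
            fh,
            indent=1,
        )
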