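"""Clone definition from CDR3 amino-acid sequences.

Unique CDR3s of equal length are merged into one clone when they differ by at
most 1 amino acid (CDR3 length 5-6) or at most 2 (length > 6); merging is
single-linkage over the resulting graph, so chains of pairwise-similar CDR3s
collapse together.  Clones supported by fewer than 2 reads are discarded and
frequencies renormalised over the survivors.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter, defaultdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

DEFAULT_MIN_READS = 2


def hamming(a: str, b: str) -> int:
    """Positional amino-acid differences between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length CDR3s")
    return sum(x != y for x, y in zip(a, b))


def merge_threshold(cdr3_length: int) -> int:
    """Maximum amino-acid differences merged into one clone: 1 for CDR3
    length 5-6, 2 for length > 6."""
    if cdr3_length < 5:
        raise ValueError("CDR3 shorter than 5 aa is not clonotyped")
    return 1 if cdr3_length <= 6 else 2


@dataclasses.dataclass
class Clone:
    clone_id: int
    cdr3_aa: str  # representative: most abundant member CDR3
    cdr3_length: int
    members: frozenset[str]
    read_count: int
    frequency: float
    v_call: str | None
    j_call: str | None

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class CloneRecord:
    """Minimal clonotyping input: one unique CDR3 observation."""

    cdr3_aa: str
    read_count: int = 1
    v_call: str | None = None
    j_call: str | None = None


def _as_records(reads: Iterable) -> list[CloneRecord]:
    records = []
    for r in reads:
        if isinstance(r, CloneRecord):
            records.append(r)
        elif isinstance(r, tuple):
            records.append(CloneRecord(*r))
        else:  # AnnotatedRead-like
            if not getattr(r, "valid", True) or r.cdr3_aa is None:
                continue
            records.append(
                CloneRecord(
                    r.cdr3_aa,
                    getattr(r, "duplicate_count", 1),
                    r.vj.v_call if r.vj else None,
                    r.vj.j_call if r.vj else None,
                )
            )
    return records


def _components(cdr3s: list[str], threshold: int) -> np.ndarray:
    """Single-linkage component label per unique CDR3 (equal lengths)."""
    n = len(cdr3s)
    if n == 1:
        return np.zeros(1, dtype=int)
    m = np.frombuffer("".join(cdr3s).encode(), dtype=np.uint8).reshape(n, -1)
    rows, cols = [], []
    # chunked pairwise Hamming to bound memory on large length classes
    step = max(1, 2_000_000 // (n * m.shape[1] + 1))
    for i0 in range(0, n, step):
        d = (m[i0 : i0 + step, None, :] != m[None, :, :]).sum(axis=2)
        r, c = np.nonzero(d <= threshold)
        rows.append(r + i0)
        cols.append(c)
    adj = csr_matrix(
        (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return connected_components(adj, directed=False)[1]


def cluster_clones(reads: Iterable, require_same_v: bool = False) -> list[Clone]:
    """Collapse annotated reads (or ``(cdr3, count, v, j)`` records) into
    clones; frequencies are over all clonotyped reads."""
    records = _as_records(reads)
    total_reads = sum(r.read_count for r in records)
    groups: dict = defaultdict(list)
    for r in records:
        key = (len(r.cdr3_aa), r.v_call) if require_same_v else len(r.cdr3_aa)
        groups[key].append(r)

    clones: list[Clone] = []
    for key in sorted(groups, key=str):
        recs = groups[key]
        length = len(recs[0].cdr3_aa)
        # collapse to unique CDR3s with multiplicity
        counts: Counter = Counter()
        vj_votes: dict[str, Counter] = defaultdict(Counter)
        for r in recs:
            counts[r.cdr3_aa] += r.read_count
            vj_votes[r.cdr3_aa][(r.v_call, r.j_call)] += r.read_count
        uniq = sorted(counts)
        labels = _components(uniq, merge_threshold(length))
        for comp in np.unique(labels):
            members = [uniq[i] for i in np.flatnonzero(labels == comp)]
            read_count = sum(counts[m] for m in members)
            rep = max(members, key=lambda m: (counts[m], _neg_lex(m)))
            votes: Counter = Counter()
            for m in members:
                votes.update(vj_votes[m])
            (v_call, j_call), _ = max(
                votes.items(), key=lambda kv: (kv[1], _neg_lex(str(kv[0])))
            )
            clones.append(
                Clone(
                    clone_id=len(clones),
                    cdr3_aa=rep,
                    cdr3_length=length,
                    members=frozenset(members),
                    read_count=read_count,
                    frequency=read_count / total_reads if total_reads else 0.0,
                    v_call=v_call,
                    j_call=j_call,
                )
            )
    return clones


class _neg_lex(str):
    """Reverses lexicographic order so max() breaks ties toward the
    alphabetically first string."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def filter_clones(clones: list[Clone], min_reads: int = DEFAULT_MIN_READS) -> list[Clone]:
    """Drop clones below the read-support floor and renormalise frequencies."""
    kept = [c for c in clones if c.read_count >= min_reads]
    if not kept:
        if clones:
            warnings.warn("all clones removed by the read-support filter")
        return []
    total = sum(c.read_count for c in kept)
    return [
        dataclasses.replace(c, frequency=c.read_count / total) for c in kept
    ]


def clone_table(clones: list[Clone]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "cdr3_aa": c.cdr3_aa,
                "cdr3_length": c.cdr3_length,
                "v_call": c.v_call,
                "j_call": c.j_call,
                "read_count": c.read_count,
                "frequency": c.frequency,
                "n_members": c.n_members,
            }
            for c in clones
        ],
        columns=[
            "clone_id", "cdr3_aa", "cdr3_length", "v_call", "j_call",
            "read_count", "frequency", "n_members",
        ],
    )
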