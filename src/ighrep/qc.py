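"""Read quality control: expected-error filtering and capped subsampling.

A read's expected error count is ``E = sum_i 10^(-Q_i/10)`` over its Phred
scores; reads with E strictly greater than the threshold (default 2) are
discarded, then up to a fixed cap (default 15,000) of the survivors are drawn
uniformly without replacement.  Subsampling is keyed on read ids so the drawn
multiset does not depend on input order for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_MAX_EE = 2.0
DEFAULT_SUBSAMPLE_CAP = 15000
DEFAULT_PHRED_OFFSET = 33


@dataclasses.dataclass
class Read:
    """A sequencing read with per-base Phred scores."""

    id: str
    seq: str
    quals: np.ndarray  # integer Phred scores

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int64)
        if len(self.seq) != len(self.quals):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        if (self.quals < 0).any():
            raise ValueError(f"read {self.id}: negative Phred score")


@dataclasses.dataclass
class QCReport:
    sample: str = ""
    n_input: int = 0
    n_pass_ee: int = 0
    n_subsampled: int = 0
    max_ee: float = DEFAULT_MAX_EE
    cap: int = DEFAULT_SUBSAMPLE_CAP
    seed: int | None = None


def read_fastq(path: str | Path, phred_offset: int = DEFAULT_PHRED_OFFSET) -> list[Read]:
    """Parse a FASTQ file (Phred+``phred_offset``)."""
    reads = []
    try:
        with open(path) as fh:
            for rid, seq, qual in FastqGeneralIterator(fh):
                quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
                quals -= phred_offset
                if (quals < 0).any():
                    raise ValueError(
                        f"{path}, read {rid!r}: quality below Phred offset {phred_offset}"
                    )
                reads.append(Read(rid.split()[0], seq.upper(), quals))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from exc
    return reads


def write_fastq(reads: list[Read], path: str | Path, phred_offset: int = DEFAULT_PHRED_OFFSET) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(int(q) + phred_offset) for q in r.quals)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def expected_errors(quals: np.ndarray | list[int]) -> float:
    """Expected number of sequencing errors from Phred scores."""
    quals = np.asarray(quals, dtype=float)
    if quals.size and (quals < 0).any():
        raise ValueError("negative Phred score")
    return float(np.sum(10.0 ** (-quals / 10.0))) if quals.size else 0.0


def filter_by_expected_errors(
    reads: list[Read], max_ee: float = DEFAULT_MAX_EE
) -> tuple[list[Read], QCReport]:
    """Keep reads with E <= max_ee (strictly greater are discarded)."""
    kept = [r for r in reads if expected_errors(r.quals) <= max_ee]
    report = QCReport(n_input=len(reads), n_pass_ee=len(kept), max_ee=max_ee)
    return kept, report


def subsample_reads(
    reads: list[Read], cap: int = DEFAULT_SUBSAMPLE_CAP, seed: int = 0
) -> list[Read]:
    """Uniform sample without replacement of up to ``cap`` reads.

    Reads are ranked by id before drawing, so the sampled multiset depends
    only on the seed and the id set, not on input order.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if len(reads) <= cap:
        return list(reads)
    order = sorted(range(len(reads)), key=lambda i: reads[i].id)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(reads), size=cap, replace=False)
    return [reads[order[i]] for i in sorted(pick)]


def run_qc(
    reads: list[Read],
    sample: str = "",
    max_ee: float = DEFAULT_MAX_EE,
    cap: int = DEFAULT_SUBSAMPLE_CAP,
    seed: int = 0,
) -> tuple[list[Read], QCReport]:
    """Expected-error filter followed by capped subsampling."""
    kept, report = filter_by_expected_errors(reads, max_ee)
    out = subsample_reads(kept, cap, seed)
    report.sample = sample
    report.n_subsampled = len(out)
    report.cap = cap
    report.seed = seed
    return out, report


def merge_read_pair(
    r1: Read,
    r2_revcomp: Read,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.10,
) -> Read | None:
    """Optional naive overlap merger for pre-merged pipelines that still
    receive pairs: slide the (already reverse-complemented) mate over the
    forward read, accept the longest overlap with mismatch rate <= 10%,
    higher-quality base wins at disagreements.  Returns None if no overlap
    qualifies."""
    s1, s2 = r1.seq, r2_revcomp.seq
    best = None
    for ov in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        a, b = s1[-ov:], s2[:ov]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm / ov <= max_mismatch_rate:
            best = ov
            break
    if best is None:
        return None
    ov = best
    seq = list(s1[: len(s1) - ov])
    quals = list(r1.quals[: len(s1) - ov])
    for k in range(ov):
        q1, q2 = r1.quals[len(s1) - ov + k], r2_revcomp.quals[k]
        if s1[len(s1) - ov + k] == s2[k]:
            seq.append(s1[len(s1) - ov + k])
            quals.append(max(q1, q2))
        elif q2 > q1:
            seq.append(s2[k])
            quals.append(q2)
        else:
            seq.append(s1[len(s1) - ov + k])
            quals.append(q1)
    seq += list(s2[ov:])
    quals += list(r2_revcomp.quals[ov:])
    return Read(r1.id, "".join(seq), np.array(quals))
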