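"""Per-sample repertoire summaries: Hill diversity, oligoclonality, CDR3
length distribution, and V/J gene usage.

The Hill (true) diversity of order q is the effective number of equally
common clones, ``D_q = (sum_i p_i^q)^(1/(1-q))`` with the q -> 1 limit
``exp(-sum p_i ln p_i)``.  Low orders weight richness, high orders weight
dominance; a panel of q in {0, 1, 2, 5} is computed with q = 5 as the
headline index (the default of the tcR-style diversity convention), recorded
in the output metadata.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .clonotype import Clone
from .germline import gene_name

DIVERSITY_Q_PANEL = (0.0, 1.0, 2.0, 5.0)
HEADLINE_Q = 5.0
DEFAULT_TOP_N = 20


def hill_diversity(frequencies, q: float) -> float:
    """Effective richness of order q of a clone frequency vector."""
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    p = np.asarray(frequencies, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty frequency vector")
    p = p / p.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def top_n_cumulative_frequency(clones: list[Clone], n: int = DEFAULT_TOP_N) -> float:
    """Percent of the repertoire carried by the n most abundant clones."""
    freqs = sorted((c.frequency for c in clones), reverse=True)
    return 100.0 * sum(freqs[:n])


def cdr3_length_summary(clones: list[Clone]) -> tuple[dict[int, int], float]:
    """Clone-level CDR3 length histogram and median (midpoint on even
    counts)."""
    lengths = sorted(c.cdr3_length for c in clones)
    hist: dict[int, int] = {}
    for ln in lengths:
        hist[ln] = hist.get(ln, 0) + 1
    return hist, float(np.median(lengths)) if lengths else float("nan")


def gene_usage(
    clones: list[Clone],
    segment: str = "V",
    level: str = "gene",
    all_genes: list[str] | None = None,
) -> pd.Series:
    """Percent of clones per (gene-collapsed) V or J call; genes listed in
    ``all_genes`` but absent from the sample appear with 0."""
    calls = [c.v_call if segment == "V" else c.j_call for c in clones]
    calls = [gene_name(c) if level == "gene" else c for c in calls if c is not None]
    usage = pd.Series(calls, dtype=object).value_counts() / max(len(calls), 1) * 100.0
    if all_genes is not None:
        names = [gene_name(g) if level == "gene" else g for g in all_genes]
        usage = usage.reindex(sorted(set(names)), fill_value=0.0)
    return usage.astype(float).sort_index()


def clone_mean_values(clones: list[Clone], annotated, value) -> np.ndarray:
    """Read-weighted mean of a per-read quantity for each clone.

    ``annotated`` are AnnotatedRead-like objects with ``cdr3_aa`` and
    ``duplicate_count``; ``value`` maps one to a float (e.g.
    ``lambda a: a.vj.v_identity_nt``).  Supports clone-pooled group tests —
    the alternative unit to per-sample means for germline-identity
    comparisons; clones without any matching read are dropped.
    """
    member_of = {m: i for i, c in enumerate(clones) for m in c.members}
    acc = np.zeros(len(clones))
    wt = np.zeros(len(clones))
    for a in annotated:
        if not getattr(a, "valid", True) or a.cdr3_aa is None:
            continue
        i = member_of.get(a.cdr3_aa)
        if i is None:
            continue
        w = getattr(a, "duplicate_count", 1)
        acc[i] += w * value(a)
        wt[i] += w
    keep = wt > 0
    return acc[keep] / wt[keep]


@dataclasses.dataclass
class RepertoireProfile:
    """Summary of one sample's filtered clone set."""

    sample_id: str
    isotype: str
    n_clones: int
    diversity: dict[float, float]
    top_n_cumfreq: float
    top_n: int
    cdr3_length_hist: dict[int, int]
    median_cdr3_length: float
    v_usage: pd.Series
    j_usage: pd.Series
    headline_q: float = HEADLINE_Q

    @property
    def headline_diversity(self) -> float:
        return self.diversity[self.headline_q]


def profile_repertoire(
    clones: list[Clone],
    sample_id: str = "",
    isotype: str = "IgG",
    q_panel=DIVERSITY_Q_PANEL,
    top_n: int = DEFAULT_TOP_N,
    v_genes: list[str] | None = None,
    j_genes: list[str] | None = None,
) -> RepertoireProfile:
    """Compute the per-sample summary over filtered (>= 2 read) clones."""
    freqs = [c.frequency for c in clones]
    hist, median = cdr3_length_summary(clones)
    diversity = {
        float(q): (hill_diversity(freqs, q) if clones else float("nan"))
        for q in q_panel
    }
    return RepertoireProfile(
        sample_id=sample_id,
        isotype=isotype,
        n_clones=len(clones),
        diversity=diversity,
        top_n_cumfreq=top_n_cumulative_frequency(clones, top_n) if clones else float("nan"),
        top_n=top_n,
        cdr3_length_hist=hist,
        median_cdr3_length=median,
        v_usage=gene_usage(clones, "V", all_genes=v_genes),
        j_usage=gene_usage(clones, "J", all_genes=j_genes),
    )


def profile_table(profiles: list[RepertoireProfile]) -> pd.DataFrame:
    """One row per sample: clone count, diversity panel, oligoclonality,
    median CDR3 length."""
    rows = []
    for p in profiles:
        row = {
            "sample_id": p.sample_id,
            "isotype": p.isotype,
            "n_clones": p.n_clones,
            "top_n_cumfreq": p.top_n_cumfreq,
            "top_n": p.top_n,
            "median_cdr3_length": p.median_cdr3_length,
            "headline_q": p.headline_q,
        }
        for q, d in p.diversity.items():
            row[f"diversity_q{q:g}"] = d
        rows.append(row)
    return pd.DataFrame(rows)
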