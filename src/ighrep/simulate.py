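"""Synthetic two-cohort IgH repertoire studies (truth tables + FASTQ).

Each donor's repertoire is a set of clones produced by a simplified V(D)J
recombination model: an ungapped germline V through the conserved Cys104, a
random in-frame junction insert, and a germline J suffix beginning inside its
CDR3 tail, so every clone's CDR3 starts at the Cys anchor and ends at the
J-encoded Trp of the WGxG motif.  Somatic hypermutation is applied as
independent per-site substitutions at region-specific rates (no indels, no
hotspot targeting).  Reads are drawn from clones with power-law multiplicity
(``P(size) proportional to rank^-alpha``) and per-base Phred scores from a
clamped normal; sequencing errors, when enabled, are drawn per base from the
base's own Phred error probability.

Two cohort presets mirror the qualitative contrasts of the hypogamma-
globulinemia study the pipeline is built for: donors who need IgG replacement
("needs_igrt_like": more clones, a more even clone-size distribution, less
somatic hypermutation, IGHV4-34/IGHV3-23-biased V usage) versus donors who do
not ("no_igrt_like": fewer clones, oligoclonal, more hypermutation).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._codec import translate
from .germline import GermlineGene, builtin_germlines, j_anchor_codon

SHM_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "J")
_STOP_AA = "*"
_BASES = np.array([ord(b) for b in "ACGT"], dtype=np.uint8)

SAMPLE_SHEET_COLUMNS = ["sample_id", "cohort", "isotype", "fastq_path"]


@dataclasses.dataclass
class SimCohortConfig:
    """Generating parameters for one cohort of donors."""

    label: str = "cohort"
    n_donors: int = 8
    clones_per_donor: int = 1000
    clone_size_exponent: float = 1.0
    v_usage_weights: dict[str, float] | None = None  # None = uniform
    shm_rate_per_region: dict[str, float] = dataclasses.field(
        default_factory=lambda: {r: 0.02 for r in SHM_REGIONS}
    )
    cdr3_length_mean: float = 15.0
    cdr3_length_sd: float = 2.0
    reads_per_sample: int = 15000
    mean_quality: float = 37.0
    quality_sd: float = 3.0
    error_from_quality: bool = True
    seed: int = 0
    isotype: str = "IgG"
    #: Dirichlet concentration scaling for per-donor V-usage jitter (0 = none)
    donor_usage_concentration: float = 50.0
    #: lognormal sigma for per-donor jitter of the clone count (0 = none)
    clones_jitter_sd: float = 0.1

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.clone_size_exponent <= 0:
            raise ValueError("clone_size_exponent must be positive")
        for region, rate in self.shm_rate_per_region.items():
            if region not in SHM_REGIONS:
                raise ValueError(f"unknown SHM region {region!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"SHM rate for {region} outside [0,1]")
        if self.v_usage_weights is not None:
            w = np.array(list(self.v_usage_weights.values()), dtype=float)
            if (w < 0).any() or w.sum() == 0:
                raise ValueError("v_usage_weights must be nonnegative, not all zero")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")

    def replace(self, **kw) -> "SimCohortConfig":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class CloneTruth:
    """Ground truth for one simulated clone."""

    clone_id: int
    v_call: str
    j_call: str
    cdr3_aa: str
    sequence: str
    true_read_count: int = 0
    region_mutations: dict[str, int] = dataclasses.field(default_factory=dict)


def _mutate_interval(
    seq: list[str], start: int, end: int, rate: float, rng: np.random.Generator
) -> int:
    """Substitute bases in [start, end) at `rate` per site, codon-safe.

    Codons (in frame 0 of the whole sequence) that would become stops are
    redrawn; returns the realised substitution count.
    """
    if rate == 0.0 or end <= start:
        return 0
    hits = start + np.flatnonzero(rng.random(end - start) < rate)
    n_mut = 0
    for cs in np.unique(hits - hits % 3):
        in_codon = hits[(hits >= cs) & (hits < cs + 3)]
        orig = seq[cs : cs + 3]
        for _ in range(30):
            trial = list(orig)
            for k in in_codon:
                trial[k - cs] = chr(rng.choice(_BASES[_BASES != ord(orig[k - cs])]))
            if translate("".join(trial)) != _STOP_AA:
                seq[cs : cs + 3] = trial
                n_mut += len(in_codon)
                break
    return n_mut


def simulate_clone(
    v_genes: list[GermlineGene],
    j_genes: list[GermlineGene],
    config: SimCohortConfig,
    rng: np.random.Generator,
    clone_id: int = 0,
    v_weights: np.ndarray | None = None,
) -> CloneTruth:
    """Draw one recombined, hypermutated clone sequence with its truth record."""
    if not v_genes or not j_genes:
        raise ValueError("germline set must contain at least one V and one J gene")
    if v_weights is None:
        if config.v_usage_weights is None:
            v_weights = np.full(len(v_genes), 1.0 / len(v_genes))
        else:
            v_weights = np.array(
                [config.v_usage_weights.get(g.name, 0.0) for g in v_genes], dtype=float
            )
            v_weights = v_weights / v_weights.sum()
    v = v_genes[rng.choice(len(v_genes), p=v_weights)]
    j = j_genes[rng.integers(len(j_genes))]

    length = int(np.clip(round(rng.normal(config.cdr3_length_mean, config.cdr3_length_sd)), 5, 30))
    anchor = j_anchor_codon(j)
    middle = length - 2  # codons between Cys104 and the J Trp
    j_tail_used = min(anchor, middle)
    n_insert = middle - j_tail_used
    insert = []
    for _ in range(n_insert):
        while True:
            codon = "".join(chr(b) for b in rng.choice(_BASES, 3))
            if translate(codon) != _STOP_AA:
                break
        insert.append(codon)
    v_len = v.v_nt_len
    seq = list(v.seq[:v_len] + "".join(insert) + j.seq[3 * (anchor - j_tail_used) :])

    # per-region SHM; the Cys104 codon is mutated at the CDR3 rate
    rates = config.shm_rate_per_region
    muts: dict[str, int] = {}
    for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
        s, e = v.region_nt_interval(region)
        if region == "FR3":
            e -= 3  # Cys104 handled with CDR3
        muts[region] = _mutate_interval(seq, s, e, rates.get(region, 0.0), rng)
    cdr3_nt_end = v_len + 3 * (middle + 1)  # through the J Trp codon
    muts["CDR3"] = _mutate_interval(seq, v_len - 3, cdr3_nt_end, rates.get("CDR3", 0.0), rng)
    muts["J"] = _mutate_interval(seq, cdr3_nt_end, len(seq), rates.get("J", 0.0), rng)

    seq_str = "".join(seq)
    cdr3_aa = translate(seq_str[v_len - 3 : cdr3_nt_end])
    return CloneTruth(clone_id, v.name, j.name, cdr3_aa, seq_str, region_mutations=muts)


def simulate_donor(
    donor_id: str,
    config: SimCohortConfig,
    v_genes: list[GermlineGene],
    j_genes: list[GermlineGene],
    rng: np.random.Generator,
) -> list[CloneTruth]:
    """Simulate a donor's clone set and its power-law read counts."""
    config.validate()
    n_clones = config.clones_per_donor
    if config.clones_jitter_sd > 0:
        n_clones = max(1, int(round(n_clones * rng.lognormal(0.0, config.clones_jitter_sd))))
    if config.v_usage_weights is None:
        base = np.full(len(v_genes), 1.0 / len(v_genes))
    else:
        base = np.array([config.v_usage_weights.get(g.name, 0.0) for g in v_genes], dtype=float)
        base = base / base.sum()
    if config.donor_usage_concentration > 0:
        alpha = np.maximum(base * config.donor_usage_concentration, 1e-6)
        weights = rng.dirichlet(alpha)
    else:
        weights = base

    clones = [
        simulate_clone(v_genes, j_genes, config, rng, clone_id=i, v_weights=weights)
        for i in range(n_clones)
    ]
    p = np.arange(1, n_clones + 1, dtype=float) ** -config.clone_size_exponent
    p /= p.sum()
    counts = rng.multinomial(config.reads_per_sample, p)
    for clone, c in zip(clones, counts):
        clone.true_read_count = int(c)
    return clones


def emit_fastq(
    truth: list[CloneTruth],
    config: SimCohortConfig,
    rng: np.random.Generator,
    path: str | Path,
    donor_id: str = "donor",
) -> int:
    """Write the donor's reads as Phred+33 FASTQ; returns the read count.

    Read ids encode donor and clone (``donor|cN|rK``) for truth joins.
    """
    n = 0
    with open(path, "w") as fh:
        for clone in truth:
            seq = np.frombuffer(clone.sequence.encode(), dtype=np.uint8)
            for k in range(clone.true_read_count):
                quals = np.clip(
                    np.rint(rng.normal(config.mean_quality, config.quality_sd, len(seq))),
                    2,
                    41,
                ).astype(int)
                read = seq.copy()
                if config.error_from_quality:
                    perr = 10.0 ** (-quals / 10.0)
                    flip = rng.random(len(seq)) < perr
                    for i in np.flatnonzero(flip):
                        read[i] = rng.choice(_BASES[_BASES != read[i]])
                fh.write(
                    f"@{donor_id}|c{clone.clone_id}|r{k}\n"
                    f"{read.tobytes().decode()}\n+\n"
                    f"{''.join(chr(q + 33) for q in quals)}\n"
                )
                n += 1
    return n


def write_truth_table(truth: list[CloneTruth], path: str | Path) -> None:
    cols = ["clone_id", "v_call", "j_call", "cdr3_aa", "true_read_count"] + [
        f"mut_{r}" for r in SHM_REGIONS
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in truth:
            row = [str(c.clone_id), c.v_call, c.j_call, c.cdr3_aa, str(c.true_read_count)]
            row += [str(c.region_mutations.get(r, 0)) for r in SHM_REGIONS]
            fh.write("\t".join(row) + "\n")


def simulate_study(
    config_a: SimCohortConfig,
    config_b: SimCohortConfig,
    outdir: str | Path,
    germlines: tuple[list[GermlineGene], list[GermlineGene]] | None = None,
    overwrite: bool = False,
) -> dict:
    """Simulate a two-cohort study; writes FASTQ, truth tables and the
    sample sheet, and returns the manifest."""
    outdir = Path(outdir)
    sheet = outdir / "sample_sheet.tsv"
    if sheet.exists() and not overwrite:
        raise FileExistsError(f"{sheet} exists; pass overwrite=True to replace")
    (outdir / "fastq").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    if germlines is None:
        germlines = builtin_germlines()
    v_genes, j_genes = germlines

    samples = []
    for cohort_index, config in enumerate((config_a, config_b)):
        config.validate()
        for d in range(config.n_donors):
            sample_id = f"{config.label}-{d + 1:02d}-{config.isotype}"
            rng = np.random.default_rng([config.seed, cohort_index, d])
            truth = simulate_donor(sample_id, config, v_genes, j_genes, rng)
            fq = outdir / "fastq" / f"{sample_id}.fastq"
            emit_fastq(truth, config, rng, fq, donor_id=sample_id)
            write_truth_table(truth, outdir / "truth" / f"{sample_id}.tsv")
            samples.append(
                {
                    "sample_id": sample_id,
                    "cohort": config.label,
                    "isotype": config.isotype,
                    "fastq_path": str(fq),
                }
            )
    with open(sheet, "w") as fh:
        fh.write("\t".join(SAMPLE_SHEET_COLUMNS) + "\n")
        for s in samples:
            fh.write("\t".join(s[c] for c in SAMPLE_SHEET_COLUMNS) + "\n")
    manifest = {
        "sample_sheet": str(sheet),
        "samples": samples,
        "config_a": dataclasses.asdict(config_a),
        "config_b": dataclasses.asdict(config_b),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# -- cohort presets -----------------------------------------------------

_LOW_SHM = {"FR1": 0.01, "CDR1": 0.02, "FR2": 0.01, "CDR2": 0.02, "FR3": 0.01,
            "CDR3": 0.02, "J": 0.01}
_HIGH_SHM = {"FR1": 0.03, "CDR1": 0.06, "FR2": 0.03, "CDR2": 0.06, "FR3": 0.03,
             "CDR3": 0.06, "J": 0.03}
_BIASED_V = {
    "IGHV1-2*01": 1.0, "IGHV2-70*01": 1.0, "IGHV3-23*01": 2.0,
    "IGHV4-30-2*01": 0.4, "IGHV4-31*01": 1.0, "IGHV4-34*01": 3.0,
    "IGHV5-51*01": 1.0, "IGHV6-1*01": 1.0,
}


def preset(name: str, **overrides) -> SimCohortConfig:
    """Named cohort presets.

    ``needs_igrt_like``: 2000 clones/donor, near-even clone sizes
    (alpha = 0.72, truth-level top-20 share about 20%), low SHM, V usage
    biased toward IGHV4-34 and IGHV3-23.  ``no_igrt_like``: 500 clones/donor,
    oligoclonal (alpha = 0.85), high SHM, uniform V usage.
    """
    presets = {
        "needs_igrt_like": dict(
            label="needs_IgG_RT",
            clones_per_donor=2000,
            clone_size_exponent=0.72,
            shm_rate_per_region=dict(_LOW_SHM),
            v_usage_weights=dict(_BIASED_V),
            seed=11,
        ),
        "no_igrt_like": dict(
            label="no_IgG_RT",
            clones_per_donor=500,
            clone_size_exponent=0.85,
            shm_rate_per_region=dict(_HIGH_SHM),
            v_usage_weights=None,
            seed=22,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    kw = presets[name]
    kw.update(overrides)
    return SimCohortConfig(**kw)


def preset_study(**overrides) -> tuple[SimCohortConfig, SimCohortConfig]:
    """The default signal-bearing study: needs-IgG-RT-like vs no-IgG-RT-like."""
    a = preset("needs_igrt_like", **{k: v for k, v in overrides.items() if k != "label"})
    b = preset("no_igrt_like", **{k: v for k, v in overrides.items() if k != "label"})
    return a, b
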