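"""End-to-end study runner: QC -> annotate -> clonotype -> stats -> compare.

Every stage's constants live in :class:`PipelineConfig`; per-sample seeds are
derived from the global seed and a hash of the sample id, so adding a sample
leaves the others' subsampling untouched.  Reruns with identical config and
inputs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotatedRead,
    GermlineDB,
    annotate_reads,
    build_junction_pssms,
    to_airr_table,
)
from .clonotype import Clone, clone_table, cluster_clones, filter_clones
from .compare import (
    compare_group_summaries,
    differential_usage,
    pca_usage,
    pearson_pairwise_complete,
)
from .germline import builtin_germlines, gene_name, read_imgt_fasta
from .qc import QCReport, read_fastq, run_qc
from .simulate import SAMPLE_SHEET_COLUMNS
from .stats import RepertoireProfile, profile_repertoire, profile_table

log = logging.getLogger("ighrep")

#: provenance of the fixed constants (logged with every run)
CONSTANT_PROVENANCE = {
    "qc.max_ee": "reads with expected errors E > 2 are discarded",
    "qc.subsample_cap": "up to 15,000 reads sampled per sample after filtering",
    "clonotyping.min_reads": "clones require at least two sequencing reads",
    "annotation.id_min": "local-alignment identity floor 50%",
    "annotation.evalue_max": "E-value ceiling 1e-3",
    "stats.top_n": "oligoclonality as cumulative frequency of the top 20 clones",
    "germline.primer_mask_nt": "first 21 nt of V genes are primer sites, masked",
    "compare.alpha": "P <= 0.05 considered significant",
}


@dataclasses.dataclass
class QCParams:
    max_ee: float = 2.0
    subsample_cap: int = 15000
    phred_offset: int = 33


@dataclasses.dataclass
class AnnotationParams:
    pssm_window: int = 5
    pssm_pseudocount: float = 1.0
    min_score_fraction: float = 0.6
    id_min: float = 50.0
    evalue_max: float = 1e-3
    prefilter_top_k: int = 3


@dataclasses.dataclass
class ClonotypeParams:
    min_reads: int = 2
    require_same_v: bool = False


@dataclasses.dataclass
class StatsParams:
    diversity_q: tuple = (0.0, 1.0, 2.0, 5.0)
    top_n: int = 20


@dataclasses.dataclass
class CompareParams:
    alpha: float = 0.05


@dataclasses.dataclass
class PipelineConfig:
    sample_sheet: str = ""
    outdir: str = "ighrep_out"
    germline_v: str | None = None  # None -> bundled synthetic references
    germline_j: str | None = None
    seed: int = 0
    qc: QCParams = dataclasses.field(default_factory=QCParams)
    annotation: AnnotationParams = dataclasses.field(default_factory=AnnotationParams)
    clonotyping: ClonotypeParams = dataclasses.field(default_factory=ClonotypeParams)
    stats: StatsParams = dataclasses.field(default_factory=StatsParams)
    compare: CompareParams = dataclasses.field(default_factory=CompareParams)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stats"]["diversity_q"] = list(self.stats.diversity_q)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        for key, sub in (
            ("qc", QCParams), ("annotation", AnnotationParams),
            ("clonotyping", ClonotypeParams), ("stats", StatsParams),
            ("compare", CompareParams),
        ):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        cfg = cls(**kw)
        cfg.stats.diversity_q = tuple(cfg.stats.diversity_q)
        return cfg


def sample_seed(global_seed: int, sample_id: str) -> int:
    """Stable per-sample seed from the global seed and the sample id."""
    return (global_seed + zlib.crc32(sample_id.encode())) % (2**31)


@dataclasses.dataclass
class SampleResult:
    sample_id: str
    cohort: str
    isotype: str
    qc: QCReport
    annotated: list[AnnotatedRead]
    clones: list[Clone]
    profile: RepertoireProfile | None
    metrics: dict[str, float]


@dataclasses.dataclass
class StudyResult:
    samples: list[SampleResult]
    profiles: pd.DataFrame
    metrics: pd.DataFrame  # samples x per-sample metrics (identity, SHM, ...)
    group_tests: dict[str, pd.DataFrame]  # per isotype
    differential_usage: dict[str, object]
    pca: dict[str, object]
    usage: dict[str, pd.DataFrame]
    correlations: dict[str, object]
    outdir: Path | None


def _sample_metrics(
    annotated: list[AnnotatedRead], clones: list[Clone], profile: RepertoireProfile | None
) -> dict[str, float]:
    """Read-weighted germline identities and per-region SHM frequencies plus
    the profile's headline statistics for one sample."""
    w = ident = jident = waa = jaa = 0.0
    mut = {r: [0, 0] for r in ("FR1", "CDR1", "FR2", "CDR2", "FR3")}
    mut_aa = {r: [0, 0] for r in ("FR1", "CDR1", "FR2", "CDR2", "FR3")}
    for a in annotated:
        if not a.valid:
            continue
        c = a.duplicate_count
        w += c
        ident += c * a.vj.v_identity_nt
        jident += c * a.vj.j_identity_nt
        waa += c * a.vj.v_identity_aa
        jaa += c * a.vj.j_identity_aa
        for r in mut:
            m, n = a.mutations.nt.get(r, (0, 0))
            mut[r][0] += c * m
            mut[r][1] += c * n
            m, n = a.mutations.aa.get(r, (0, 0))
            mut_aa[r][0] += c * m
            mut_aa[r][1] += c * n
    out: dict[str, float] = {}
    if w > 0:
        out.update(
            v_identity_nt=ident / w,
            j_identity_nt=jident / w,
            v_identity_aa=waa / w,
            j_identity_aa=jaa / w,
        )
    for r, (m, n) in mut.items():
        out[f"mutfreq_nt_{r}"] = m / n if n else np.nan
    for r, (m, n) in mut_aa.items():
        out[f"mutfreq_aa_{r}"] = m / n if n else np.nan
    if profile is not None:
        out["n_clones"] = profile.n_clones
        out["top_n_cumfreq"] = profile.top_n_cumfreq
        out["median_cdr3_length"] = profile.median_cdr3_length
        for q, d in profile.diversity.items():
            out[f"diversity_q{q:g}"] = d
    return out


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks required columns {missing}")
    return sheet


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> StudyResult:
    """Run the full study described by a sample sheet."""
    outdir = Path(config.outdir)
    if write_outputs:
        for sub in ("airr", "clones", "compare"):
            (outdir / sub).mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    if config.germline_v:
        v_genes = read_imgt_fasta(config.germline_v, "V")
        j_genes = read_imgt_fasta(config.germline_j, "J")
    else:
        v_genes, j_genes = builtin_germlines()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pssms = build_junction_pssms(
            v_genes,
            j_genes,
            window_half_width=config.annotation.pssm_window,
            pseudocount=config.annotation.pssm_pseudocount,
            min_score_fraction=config.annotation.min_score_fraction,
        )
    db = GermlineDB(v_genes, j_genes, top_k=config.annotation.prefilter_top_k)
    for key, why in CONSTANT_PROVENANCE.items():
        log.info("constant %s: %s", key, why)

    sheet = read_sample_sheet(config.sample_sheet)
    results: list[SampleResult] = []
    qc_rows = []
    attrition = []
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        seed = sample_seed(config.seed, sid)
        reads = read_fastq(row["fastq_path"], config.qc.phred_offset)
        kept, qc_report = run_qc(
            reads, sid, config.qc.max_ee, config.qc.subsample_cap, seed
        )
        annotated, ann_report = annotate_reads(
            kept, db, pssms, config.annotation.id_min, config.annotation.evalue_max
        )
        clones = filter_clones(
            cluster_clones(annotated, config.clonotyping.require_same_v),
            config.clonotyping.min_reads,
        )
        n_clonotyped = sum(c.read_count for c in clones)
        profile = None
        if clones:
            profile = profile_repertoire(
                clones,
                sid,
                row["isotype"],
                config.stats.diversity_q,
                config.stats.top_n,
                v_genes=[g.name for g in v_genes],
                j_genes=[g.name for g in j_genes],
            )
        else:
            warnings.warn(
                f"sample {sid} yielded zero clones and is excluded from cohort statistics"
            )
        metrics = _sample_metrics(annotated, clones, profile)
        results.append(
            SampleResult(sid, row["cohort"], row["isotype"], qc_report, annotated, clones, profile, metrics)
        )
        qc_rows.append(dataclasses.asdict(qc_report))
        attrition.append(
            {
                "sample_id": sid,
                "n_input": qc_report.n_input,
                "n_pass_ee": qc_report.n_pass_ee,
                "n_subsampled": qc_report.n_subsampled,
                "n_annotated": ann_report.n_valid_reads,
                "n_clonotyped": n_clonotyped,
            }
        )
        if write_outputs:
            to_airr_table(annotated).to_csv(outdir / "airr" / f"{sid}.tsv", sep="\t", index=False)
            clone_table(clones).to_csv(outdir / "clones" / f"{sid}.tsv", sep="\t", index=False)

    profiles = profile_table([r.profile for r in results if r.profile is not None])
    metrics = pd.DataFrame(
        {r.sample_id: r.metrics for r in results if r.profile is not None}
    ).T
    labels_all = pd.Series(
        {r.sample_id: r.cohort for r in results if r.profile is not None}
    )
    isotypes = pd.Series(
        {r.sample_id: r.isotype for r in results if r.profile is not None}
    )

    group_tests: dict[str, pd.DataFrame] = {}
    diff: dict[str, object] = {}
    pca: dict[str, object] = {}
    usage_mats: dict[str, pd.DataFrame] = {}
    correlations: dict[str, object] = {}
    for iso in sorted(isotypes.unique()):
        ids = isotypes.index[isotypes == iso]
        labels = labels_all.loc[ids]
        usage = pd.DataFrame(
            {
                r.sample_id: r.profile.v_usage
                for r in results
                if r.profile is not None and r.sample_id in set(ids)
            }
        ).T
        usage_mats[iso] = usage
        if labels.nunique() == 2 and labels.value_counts().min() >= 2:
            group_tests[iso] = compare_group_summaries(
                metrics.loc[ids], labels, config.compare.alpha
            )
            diff[iso] = differential_usage(usage, labels, config.compare.alpha)
            pca[iso] = pca_usage(usage)
            # within-cohort all-by-all correlation of the per-sample metrics
            for cohort in labels.unique():
                sub = metrics.loc[ids[labels == cohort]]
                if len(sub) >= 3:
                    correlations[f"{cohort}_{iso}"] = pearson_pairwise_complete(
                        sub, config.compare.alpha
                    )

    result = StudyResult(
        samples=results,
        profiles=profiles,
        metrics=metrics,
        group_tests=group_tests,
        differential_usage=diff,
        pca=pca,
        usage=usage_mats,
        correlations=correlations,
        outdir=outdir if write_outputs else None,
    )
    if write_outputs:
        pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        pd.DataFrame(attrition).to_csv(outdir / "attrition.tsv", sep="\t", index=False)
        profiles.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
        metrics.rename_axis("sample_id").to_csv(outdir / "metrics.tsv", sep="\t")
        for iso, mat in usage_mats.items():
            mat.rename_axis("sample_id").to_csv(outdir / f"usage_V_{iso}.tsv", sep="\t")
        for iso, t in group_tests.items():
            t.to_csv(outdir / "compare" / f"group_tests_{iso}.tsv", sep="\t", index=False)
        for iso, d in diff.items():
            d.table.to_csv(outdir / "compare" / f"diff_usage_V_{iso}.tsv", sep="\t", index=False)
        for iso, p in pca.items():
            p.scores.rename_axis("sample_id").to_csv(
                outdir / "compare" / f"pca_scores_{iso}.tsv", sep="\t"
            )
        for key, c in correlations.items():
            c.masked_r.rename_axis("feature").to_csv(
                outdir / "compare" / f"correlation_{key}.tsv", sep="\t"
            )
        manifest = {
            "ighrep_version": __version__,
            "config": config.as_dict(),
            "constants_provenance": CONSTANT_PROVENANCE,
            "attrition": attrition,
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return result
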