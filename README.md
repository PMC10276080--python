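# ighrep

IgG/IgM heavy-chain B-cell-receptor repertoire analysis for two-cohort
clinical studies — built for the question of which hypogammaglobulinemia
patients need immunoglobulin replacement therapy (IgG-RT), and usable for
any two-group IgH amplicon comparison.

The pipeline takes per-sample FASTQ amplicon reads and a germline V/J
reference and produces, per sample and per cohort:

- **Read QC** — expected-error filtering (`E = Σ 10^(-Q/10)`, discard
  `E > 2`) and random subsampling to a fixed cap (default 15,000 reads).
- **Region annotation** — framework/CDR junction location by log-odds
  PSSMs decoded jointly over all six junctions, CDR3 extraction
  (Cys104…Trp), V/J assignment by Smith-Waterman local alignment with
  Karlin-Altschul E-values, germline identity at nt and aa level, and
  per-region SHM tallies with the 21-nt primer mask excluded.
- **Clonotyping** — unique CDR3s of equal length merged at ≤1 aa mismatch
  (length 5–6) or ≤2 (length >6), single linkage, and a ≥2-read clone
  filter.
- **Repertoire statistics** — clone counts, Hill (true) diversity
  `D_q = (Σ p_i^q)^(1/(1−q))` for q ∈ {0,1,2,5}, top-20 cumulative
  frequency (oligoclonality), CDR3-length distribution, V/J gene usage.
- **Cohort inference** — Wilcoxon rank-sum group comparisons, per-V-gene
  differential usage with Benjamini-Hochberg correction, PCA of
  `log2(usage+1)`, and pairwise-complete Pearson correlation of repertoire
  and immune features.

A synthetic two-cohort study generator (`ighrep.simulate`) with truth
tables, power-law clone sizes, region-specific SHM and quality-derived
sequencing errors ships as first-class, tested code; its presets mirror the
contrasts of the motivating study (more clones, more even repertoires,
less SHM, IGHV4-34-biased usage in the cohort needing IgG-RT).

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from ighrep.simulate import preset_study, simulate_study
from ighrep.pipeline import PipelineConfig, run_pipeline

a, b = preset_study(n_donors=4, reads_per_sample=1000)   # desk-scale demo
simulate_study(a, b, "study/")

cfg = PipelineConfig(sample_sheet="study/sample_sheet.tsv", outdir="results/", seed=1)
res = run_pipeline(cfg)

print(res.profiles[["sample_id", "n_clones", "diversity_q5", "top_n_cumfreq"]].round(1).to_string(index=False))
gt = res.group_tests["IgG"].set_index("metric")
for m in ("n_clones", "diversity_q5", "top_n_cumfreq", "v_identity_nt"):
    r = gt.loc[m]
    print(f"{m}: needs-IgG-RT {r['mean_needs_IgG_RT']:.1f} vs no-IgG-RT {r['mean_no_IgG_RT']:.1f} (p = {r['p']:.4f})")
r = res.differential_usage["IgG"].table.set_index("gene").loc["IGHV4-34"]
print(f"IGHV4-34 usage: {r['mean_needs_IgG_RT']:.1f}% vs {r['mean_no_IgG_RT']:.1f}% (BH-adjusted p = {r['p_adj']:.4f})")
```

prints

```
          sample_id  n_clones  diversity_q5  top_n_cumfreq
needs_IgG_RT-01-IgG       173          31.9           35.1
needs_IgG_RT-02-IgG       173          28.3           36.9
needs_IgG_RT-03-IgG       156          22.8           39.8
needs_IgG_RT-04-IgG       185          29.5           34.4
   no_IgG_RT-01-IgG       168          16.8           49.0
   no_IgG_RT-02-IgG       166          13.4           49.2
   no_IgG_RT-03-IgG       152          14.1           51.4
   no_IgG_RT-04-IgG       162          17.2           49.0
n_clones: needs-IgG-RT 171.8 vs no-IgG-RT 162.0 (p = 0.1913)
diversity_q5: needs-IgG-RT 28.1 vs no-IgG-RT 15.4 (p = 0.0286)
top_n_cumfreq: needs-IgG-RT 36.5 vs no-IgG-RT 49.7 (p = 0.0286)
v_identity_nt: needs-IgG-RT 98.8 vs no-IgG-RT 96.5 (p = 0.0286)
IGHV4-34 usage: 29.3% vs 12.8% (BH-adjusted p = 0.2286)
```

Reading the output: each row is one donor's filtered (≥2-read) clone set.
The needs-IgG-RT-like cohort shows higher order-5 Hill diversity (28.1 vs
15.4 effective clones), lower oligoclonality (top-20 clones carry 36.5% of
reads vs 49.7%), and higher germline identity (98.8% vs 96.5%, i.e. less
somatic hypermutation) — the planted contrasts, each already significant at
the exact Wilcoxon minimum for 4 vs 4 donors (p = 0.0286).  Clone-count and
per-gene usage contrasts need the full 8-vs-8 design to clear α = 0.05
after multiplicity correction.

The same pipeline runs from the shell:

```bash
ighrep simulate --preset contrast --out study/ --donors 8 --reads 15000
ighrep run-all --sample-sheet study/sample_sheet.tsv --out results/ --seed 1
ighrep qc --fastq sample.fastq --out filtered.fastq --max-ee 2 --cap 15000 --seed 7
```

`run-all` writes per-sample AIRR-style rearrangement TSVs, clone tables,
QC/attrition reports, per-sample profiles and metrics, usage matrices,
differential-usage and group-test tables, PCA scores, and within-cohort
correlation matrices under the output directory.  Real IMGT germline FASTA
files (gapped V, plain J) can replace the bundled synthetic reference via
`germline_v`/`germline_j` in the config.

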