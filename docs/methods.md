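# Methods

`ighrep` reimplements, as a tested and reusable pipeline, a B-cell-receptor
heavy-chain (IgH) repertoire analysis used to compare hypogammaglobulinemia
patient cohorts: read quality control, framework/CDR region annotation,
clonotype definition, somatic-hypermutation (SHM) and germline-identity
profiling, Hill-diversity and V/J-usage statistics, and two-cohort
inference.  A synthetic repertoire generator with the same statistical
structure provides download-free validation studies.

## Read quality control

The expected error count of a read is `E = sum_i 10^(-Q_i/10)` over its
Phred scores.  Reads with `E > 2` are discarded — the boundary `E = 2` is
kept, a literal reading of the "discard above 2" rule.  After filtering, up
to 15,000 reads per sample (configurable) are drawn uniformly without
replacement; reads are ranked by id before drawing so the sampled multiset
depends only on the seed and the id set, not on file order.  `N` bases carry
their stated Phred probability into `E` and never match in downstream
alignment.  Paired-end merging is not a pipeline stage; an optional naive
overlap merger (minimum overlap 20 nt, mismatch rate <= 10%, higher-quality
base wins) is available for callers that need it.  FASTQ is assumed
Phred+33; the offset is configurable.

## Germline references and coordinates

V references are IMGT-gapped ('.' gaps, 3 gapped nt per IMGT codon), with
the standard region map FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3
66–104 (Cys104 closing FR3).  All internal coordinates are 0-based half-open
on ungapped sequences; IMGT numbering appears only in region labels and
positional outputs.  J references are ungapped and carry no region map —
their germline identity is reported over the whole alignment.  The first 21
nt (7 codons) of every V gene are amplification-primer binding sites and are
excluded from all mutation counting.

The bundled reference (`ighrep/data/synthetic_*.fasta`) is a synthetic
stand-in generated by `synthetic_germline_set`: 8 V alleles (named after
common IGHV genes so usage outputs read naturally; pairwise < 85% nt
identity; conserved Cys23/Trp41/Cys104; gene-specific CDR1/CDR2 lengths
realised as IMGT gaps) and 4 J alleles with WGxG FR4 motifs.  Real IMGT
release files load through the same reader; usage statistics collapse
alleles to genes (name truncated at `*`).

## Region annotation

One position-specific scoring matrix (PSSM) is built per framework/CDR
junction (FR1/CDR1, CDR1/FR2, FR2/CDR2, CDR2/FR3, FR3/CDR3, CDR3/FR4) from
the amino-acid windows flanking that junction across the references:
log2-odds of `(count + pseudocount) / (n + 20*pseudocount)` against a
uniform background, window half-width 5 aa, pseudocount 1.  When a
reference boundary truncates one flank (the FR3/CDR3 junction has no
germline right flank), the other flank is extended so the total width stays
10 aa where capacity allows.  Each PSSM's acceptance threshold is 60% of the
mean self-score of its training windows.  These constants are exposed in the
pipeline configuration.

For each read, all three frames are translated and each PSSM scored at
every placement.  Boundaries are decoded jointly: a dynamic program over
the six-junction chain maximises the total score subject to spacing bands
of +-30% around the germline-expected region lengths and a CDR3 span of
5–30 aa.  Joint decoding was chosen over independent per-junction argmaxes
because the FR3/CDR3 junction (half-window only) occasionally mis-peaks
under SHM; the constrained decode recovers simulated truth boundaries
exactly across SHM 0–5% while random sequences still fail.  A frame is
accepted when its total score reaches the summed thresholds and the
translation is stop-free through the CDR3 end; otherwise the read is
dropped and counted.

CDR3 is reported from the Cys104 anchor through the J-motif Trp, inclusive
of both anchors (configurable); it is valid when at least 5 aa with no stop
or untranslatable codon.  Reads without a valid CDR3 are excluded from
clonotyping even when V assignment succeeds.

## V/J assignment and mutation profiling

Reads are locally aligned (Smith-Waterman, affine gaps; match +1, mismatch
−1, gap open −4, gap extend −1) against every V and J reference.  E-values
use the Karlin-Altschul form `K*m*n*exp(-lambda*S)` with `lambda` solved
from the score scheme (ln 3 for +1/−1 at uniform composition) and `K` fixed
at 0.333, a calibrated constant for this scheme; with hit scores in the
hundreds the 1e-3 gate is never marginal.  Candidates must reach 50% nt
identity and E <= 1e-3; the lowest E-value wins, ties broken by higher
identity then name.  An 8-mer-sharing prefilter (usearch-style heuristic)
shortlists the top 3 V candidates by default; `top_k=0` aligns all, and the
tests verify the shortlisted winner equals the exhaustive one.  Identity is
matches over aligned columns at the nucleotide level and, through
codon-aware translation of contiguously aligned germline codons, at the
amino-acid level; both are always computed, matching reporting conventions
that use nucleotide identity for IgG and amino-acid identity for IgM.

Mismatches along the aligned V gene are tallied per region at nt and aa
level, excluding germline positions inside the 21-nt primer mask; a region
not covered by the alignment reports zero aligned positions (undefined
frequency, not zero mutations).  Per-IMGT-position mutation frequencies
(read-weighted) support motif queries such as the IGHV4-34 FR1 hydrophobic
patch.  Identical read sequences are annotated once and carried with their
multiplicity (`duplicate_count`), which also makes the per-sample runtime
scale with unique sequences rather than reads.

## Clonotyping

Unique CDR3 amino-acid sequences of equal length are merged into one clone
when they differ by at most 1 aa (length 5–6) or at most 2 aa (length > 6);
components are taken under single linkage, so pairwise-similar chains
collapse.  Lengths never merge across brackets (Hamming distance is defined
only for equal lengths; SHM is modelled without indels for the same
reason).  Clustering is on CDR3 alone; V/J calls are read-count-weighted
majority votes, and a `require_same_v` flag conditions clustering on the V
call for callers who want it.  Clones with fewer than 2 reads are removed
and frequencies renormalised.  The representative CDR3 is the most abundant
member (ties alphabetical).

## Repertoire statistics

Per sample, over filtered clones: clone count; Hill (true) diversity
`D_q = (sum p_i^q)^(1/(1-q))` (limit `exp(-sum p ln p)` at q = 1) for a
panel q in {0, 1, 2, 5}, with q = 5 as the headline index following the
cited diversity convention's default and recorded in output metadata;
cumulative frequency of the top 20 clones (oligoclonality); clone-level
CDR3-length histogram and median; percent-of-clones V/J usage at gene
level, absent genes reported as 0.  Clone read frequencies (not unique
sequence frequencies) enter the diversity.

## Two-cohort inference

The Wilcoxon rank-sum test is the single group-comparison test throughout:
exact null distribution when the combined sample is <= 25 without ties,
otherwise the normal approximation with tie and continuity corrections
(delegated to scipy; an enumeration oracle pins the exact branch in tests).
Per-V-gene usage tests are Benjamini–Hochberg adjusted within one isotype's
gene family (genes with zero usage everywhere are excluded from the family
size); `bh_adjust` delegates to statsmodels with a brute-force step-up
oracle in tests.  PCA operates on `log2(percent usage + 1)`, columns
centred, components by SVD with percent variance summing to 100 and signs
fixed so each component's largest-magnitude loading is positive.  Pearson
correlations between per-sample features use pairwise-complete
observations: each pair restricted to samples where both values exist, at
least 3 complete pairs, two-sided t test with n−2 degrees of freedom, and a
masked matrix keeping correlations with p <= 0.05.  Germline-identity and
mutation-frequency comparisons use per-sample (read-weighted) means by
default to avoid pseudo-replication; the clone-pooled unit (one value per
clone, reproducing clone-level boxplot conventions) is available through
`stats.clone_mean_values` and the same rank-sum test.

## Synthetic study generator

Each clone is a simplified V(D)J product: ungapped germline V through
Cys104, an in-frame random junction insert, and a germline J suffix
starting inside its CDR3 tail, so CDR3 runs Cys…Trp by construction.  D
segments are not modelled (the analysis assigns only V and J).  CDR3
lengths are a discretised normal (mean 15 aa, sd 2, clamped to 5–30),
matching the observed median of 15.  SHM is independent per-site
substitution at region-specific rates; codons that would become stops are
redrawn, and no indels or WRC/GYW hotspot targeting are simulated.  Clone
sizes follow `P(size) ∝ rank^-alpha`; read counts are a multinomial draw so
they sum exactly to `reads_per_sample`.  Per-base Phred scores are a
clamped normal (default mean 37, sd 3) and sequencing errors, when enabled,
flip each base with its own Phred probability.  Donor-level realism comes
from Dirichlet jitter of the V-usage weights and lognormal jitter of the
clone count; read ids encode donor and clone for truth joins.

Two presets mirror the study's qualitative contrasts.  `needs_igrt_like`:
2000 clones/donor, alpha = 0.72 (truth-level top-20 share ≈ 20%), low SHM
(FR 1%, CDR 2%), V usage biased toward IGHV4-34 (weight 3) and IGHV3-23
(weight 2) with IGHV4-30-2 depleted.  `no_igrt_like`: 500 clones/donor,
alpha = 0.85 (top-20 ≈ 42%), high SHM (FR 3%, CDR 6%), uniform usage.  The
exponents were fixed from the closed-form rank-weight sums to reproduce the
reported cohort-level top-20 cumulative frequencies at the preset clone
counts; the default `reads_per_sample` is 15,000, the subsampling cap.

What the generator does not emulate: paired-end read structure, primer or
adapter artefacts, chimeras, hotspot-clustered SHM, indels, clonal lineage
structure within a clone, isotype-specific repertoire differences beyond
the configured parameters.  Passing recovery tests therefore demonstrate
the pipeline's correctness under its own model assumptions, not performance
on arbitrary real libraries.

## Problem sizes used in validation

The bundled validation suite and `scripts/acceptance.py` run the preset
study shape (8 vs 8 donors, preset clone counts and SHM contrasts) at
desk-scale read depth — 1,500–2,500 reads per sample rather than 15,000 —
and 5 replicate studies for the power checks plus 6 identical-cohort null
studies (6 donors, 800 reads) for type-I calibration.  The planted
contrasts are strong enough that detection power is essentially unchanged
at this depth, while a full study completes in about two minutes on one
core.  Formula-level checks (expected errors, Hill diversity, BH, Pearson,
Wilcoxon, clonotype components) use >= 1,000 random instances against
brute-force oracles.

## Numerical and degenerate-input choices

Ambiguous bases encode to a fifth symbol that never matches and translates
to `X`; codons containing them are untranslatable.  Empty quality vectors
have `E = 0`; an empty frequency vector is a diversity error; a sample
yielding zero clones is excluded from cohort statistics with a warning
rather than failing the run.  A constant usage matrix yields zero variance
and zero scores in PCA.  Zero-variance feature pairs are undefined (NaN) in
correlation, not errors.  Per-sample seeds derive from the global seed plus
a CRC32 of the sample id, so adding a sample never perturbs the others;
reruns with identical configuration and inputs are byte-identical.

## Known limitations

No D-gene assignment, allele inference, or lineage reconstruction; no
indel-aware SHM measurement (an indel-bearing read will align with gaps and
its shifted codons count as mismatches); clonotyping assumes equal-length
CDR3s; the Karlin-Altschul `K` is a scheme-level constant rather than
re-estimated per database; the bundled germline set is synthetic, so
absolute usage percentages are meaningful only within simulated studies.
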