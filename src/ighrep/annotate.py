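"""Read annotation: PSSM junction location, CDR3 extraction, V/J assignment,
germline identity, and per-region mutation counting.

Framework/CDR boundaries are located by sliding position-specific scoring
matrices (log-odds over the amino-acid windows flanking each junction in the
germline references) over all three reading frames and accepting the frame
whose best junction positions are collinear with germline spacing.  V and J
genes are then assigned by local alignment against every reference (an
8-mer-sharing prefilter optionally shortlists candidates), the winner being
the hit with the lowest Karlin-Altschul E-value subject to identity >= 50%
and E <= 1e-3.  Mismatches along the aligned V gene are tallied per IMGT
region, excluding the 5' primer-binding mask (first 21 nt by default).
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from ._codec import AA_STOP, AA_X, decode_aa, encode_nt, translate_codes
from .align import LocalAlignment, evalue, smith_waterman
from .germline import GermlineGene, j_anchor_codon
from .qc import Read

V_JUNCTIONS = ("FR1/CDR1", "CDR1/FR2", "FR2/CDR2", "CDR2/FR3", "FR3/CDR3")
J_JUNCTION = "CDR3/FR4"
CDR3_MIN_AA = 5
CDR3_MAX_AA = 30

DEFAULT_ID_MIN = 50.0
DEFAULT_EVALUE_MAX = 1e-3


@dataclasses.dataclass
class JunctionPssm:
    """Log-odds matrix for the window flanking one framework/CDR junction."""

    junction: str
    window_left: int
    window_right: int
    matrix: np.ndarray  # (width, 22) log2 odds
    pseudocount: float
    background: np.ndarray
    min_score: float

    @property
    def width(self) -> int:
        return self.window_left + self.window_right

    def scores(self, aa_codes: np.ndarray) -> np.ndarray:
        """Score of every boundary placement b in [window_left,
        len(aa) - window_right]; returns an array indexed by b."""
        w = self.width
        if len(aa_codes) < w:
            return np.array([])
        win = np.lib.stride_tricks.sliding_window_view(aa_codes, w)
        return self.matrix[np.arange(w)[None, :], win.astype(np.int64)].sum(axis=1)

    def score_window(self, aa_codes: np.ndarray, boundary: int) -> float:
        w = aa_codes[boundary - self.window_left : boundary + self.window_right]
        return float(self.matrix[np.arange(len(w)), w.astype(np.int64)].sum())


@dataclasses.dataclass
class PssmSet:
    pssms: dict[str, JunctionPssm]
    expected_spacing: dict[str, float]  # region -> mean ungapped aa length

    @property
    def total_min_score(self) -> float:
        return sum(p.min_score for p in self.pssms.values())


def _log_odds(
    windows: list[np.ndarray], width: int, pseudocount: float, background: np.ndarray
) -> np.ndarray:
    counts = np.zeros((width, 22))
    for w in windows:
        for k, aa in enumerate(w):
            counts[k, aa] += 1
    n = len(windows)
    freq = (counts + pseudocount) / (n + 20.0 * pseudocount)
    return np.log2(freq / background[None, :])


def build_junction_pssms(
    v_genes: list[GermlineGene],
    j_genes: list[GermlineGene],
    window_half_width: int = 5,
    pseudocount: float = 1.0,
    min_score_fraction: float = 0.6,
) -> PssmSet:
    """Build one PSSM per framework/CDR junction from the reference set.

    Windows extending past a reference are shrunk (with a warning); the
    acceptance threshold of each PSSM is ``min_score_fraction`` of the mean
    self-score of its training windows.
    """
    if not v_genes or not j_genes:
        raise ValueError("need at least one V and one J germline gene")
    hw = window_half_width
    background = np.full(22, 1.0 / 20.0)
    pssms: dict[str, JunctionPssm] = {}

    def _fit_window(raw: list[tuple[np.ndarray, int]], junction: str) -> tuple[int, int]:
        """Largest (left, right) half-windows that fit every reference; a side
        shrunk by a reference boundary is compensated on the other side so the
        total width stays 2*hw where capacity allows."""
        cap_l = min(b for _, b in raw)
        cap_r = min(len(aa) - b for aa, b in raw)
        wl, wr = min(hw, cap_l), min(hw, cap_r)
        wl = min(cap_l, wl + (hw - wr))
        wr = min(cap_r, wr + (2 * hw - wl - wr))
        if wl + wr < 2 * hw:
            warnings.warn(
                f"junction {junction}: window shrunk to ({wl},{wr}) to fit references"
            )
        return wl, wr

    def _build(raw: list[tuple[np.ndarray, int]], junction: str) -> JunctionPssm:
        wl, wr = _fit_window(raw, junction)
        windows = [aa[b - wl : b + wr] for aa, b in raw]
        mat = _log_odds(windows, wl + wr, pseudocount, background)
        self_scores = [
            mat[np.arange(len(w)), w.astype(np.int64)].sum() for w in windows
        ]
        return JunctionPssm(
            junction, wl, wr, mat, pseudocount, background,
            min_score_fraction * float(np.mean(self_scores)),
        )

    v_aa = {g.name: translate_codes(g.codes) for g in v_genes}
    for junction in V_JUNCTIONS:
        left_region = junction.split("/")[0]
        raw = [
            (v_aa[g.name], g.region_aa_interval_ungapped(left_region)[1])
            for g in v_genes
        ]
        pssms[junction] = _build(raw, junction)

    # CDR3/FR4 junction trained on J references around the conserved Trp
    raw_j = [
        (translate_codes(g.codes), j_anchor_codon(g) + 1)  # boundary after Trp
        for g in j_genes
    ]
    pssms[J_JUNCTION] = _build(raw_j, J_JUNCTION)

    spacing = {
        region: float(
            np.mean([
                g.region_aa_interval_ungapped(region)[1]
                - g.region_aa_interval_ungapped(region)[0]
                for g in v_genes
            ])
        )
        for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3")
    }
    return PssmSet(pssms, spacing)


@dataclasses.dataclass
class RegionHit:
    """Accepted frame with junction boundaries (aa indices of the frame's
    translation) and derived nucleotide intervals on the read."""

    frame: int
    boundaries: dict[str, int]
    total_score: float
    region_nt: dict[str, tuple[int, int]]
    region_aa: dict[str, tuple[int, int]]  # frame-translation aa indices
    aa_codes: np.ndarray


def _windowed_max(prev: np.ndarray, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """For each position b, max and argmax of ``prev`` over [b-hi, b-lo]."""
    n = len(prev)
    width = hi - lo + 1
    padded = np.full(n + width - 1, -np.inf)
    padded[width - 1 :] = prev  # padded[b - lo + (width-1) - k] ...
    win = np.lib.stride_tricks.sliding_window_view(padded, width)
    # win[i] = padded[i : i+width] = prev[i-width+1 : i+1] (clipped)
    idx = np.arange(n) - lo  # window ending at b - lo
    idx = np.clip(idx, 0, n - 1)
    rows = win[idx]
    arg = rows.argmax(axis=1)
    best = rows[np.arange(n), arg]
    src = (idx - (width - 1)) + arg  # position in prev
    invalid = np.arange(n) - lo < 0
    best[invalid] = -np.inf
    return best, src


def locate_regions(
    read: Read | str, pssm_set: PssmSet, spacing_tolerance: float = 0.30
) -> RegionHit | None:
    """Find FR/CDR boundaries by scanning all three frames; None on failure.

    Per frame, each junction PSSM is slid over the translation and the
    jointly best collinear placement — boundary spacings within the tolerance
    band around the germline expectation, CDR3 between 5 and 30 aa — is found
    by dynamic programming over the junction chain; the frame is accepted
    when the total score reaches the summed per-junction thresholds and the
    translation is stop-free through the CDR3 end.
    """
    seq = read.seq if isinstance(read, Read) else read
    codes = encode_nt(seq)
    exp = pssm_set.expected_spacing
    tol = spacing_tolerance
    junctions = (*V_JUNCTIONS, J_JUNCTION)
    # spacing bands between consecutive junctions (in aa)
    bands = [
        (int(np.ceil(exp[r] * (1 - tol))), int(np.floor(exp[r] * (1 + tol))))
        for r in ("CDR1", "FR2", "CDR2", "FR3")
    ] + [(CDR3_MIN_AA - 1, CDR3_MAX_AA - 1)]  # Cys..Trp span = CDR3 len - 1
    best: RegionHit | None = None
    for frame in range(3):
        aa = translate_codes(codes, frame)
        if len(aa) < 40:
            continue
        n = len(aa)
        scores = []
        ok = True
        for junction in junctions:
            p = pssm_set.pssms[junction]
            sc = p.scores(aa)
            if sc.size == 0:
                ok = False
                break
            full = np.full(n, -np.inf)
            k = min(len(sc), n - p.window_left)  # boundary at the very end unusable
            full[p.window_left : p.window_left + k] = sc[:k]
            scores.append(full)
        if not ok:
            continue
        # DP over the junction chain under the spacing bands
        cum = scores[0].copy()
        back: list[np.ndarray] = []
        for k in range(1, 6):
            lo, hi = bands[k - 1]
            prev_best, src = _windowed_max(cum, lo, hi)
            cum = scores[k] + prev_best
            back.append(src)
        if not np.isfinite(cum).any():
            continue
        b6 = int(np.argmax(cum))
        total = float(cum[b6])
        if total < pssm_set.total_min_score:
            continue
        b = [b6]
        for k in range(4, -1, -1):
            b.append(int(back[k][b[-1]]))
        b = b[::-1]
        bounds = dict(zip(junctions, b))
        if (aa[: b[5]] == AA_STOP).any():
            continue
        fr1_start = max(0, b[0] - int(round(exp["FR1"])))
        nt = {}
        aa_iv = {
            "FR1": (fr1_start, b[0]),
            "CDR1": (b[0], b[1]),
            "FR2": (b[1], b[2]),
            "CDR2": (b[2], b[3]),
            "FR3": (b[3], b[4]),
            "CDR3": (b[4] - 1, b[5]),
            "FR4": (b[5], len(aa)),
        }
        for region, (s, e) in aa_iv.items():
            nt[region] = (frame + 3 * s, frame + 3 * e)
        hit = RegionHit(frame, bounds, total, nt, aa_iv, aa)
        if best is None or hit.total_score > best.total_score:
            best = hit
    return best


def extract_cdr3(hit: RegionHit) -> str | None:
    """CDR3 amino acids (Cys104 anchor through the J-motif Trp, inclusive);
    None when absent, shorter than 5 aa, or containing a stop/untranslatable
    codon."""
    s, e = hit.region_aa["CDR3"]
    aa = hit.aa_codes[s:e]
    if len(aa) < CDR3_MIN_AA or (aa == AA_STOP).any() or (aa == AA_X).any():
        return None
    return decode_aa(aa)


@dataclasses.dataclass
class VJAssignment:
    v_call: str
    j_call: str
    v_evalue: float
    j_evalue: float
    v_identity_nt: float
    j_identity_nt: float
    v_identity_aa: float
    j_identity_aa: float
    v_alignment: LocalAlignment
    j_alignment: LocalAlignment


class GermlineDB:
    """Alignment database over a germline set with an optional k-mer-sharing
    prefilter (``top_k`` candidates fully aligned; ``top_k=0`` aligns all)."""

    def __init__(
        self,
        v_genes: list[GermlineGene],
        j_genes: list[GermlineGene],
        top_k: int = 3,
        kmer: int = 8,
    ):
        self.v_genes = list(v_genes)
        self.j_genes = list(j_genes)
        self.top_k = top_k
        self.kmer = kmer
        self.v_db_len = sum(len(g.seq) for g in v_genes)
        self.j_db_len = sum(len(g.seq) for g in j_genes)
        self._v_kmers = [self._kmer_set(g.codes) for g in v_genes]
        self.by_name = {g.name: g for g in [*v_genes, *j_genes]}

    def _kmer_set(self, codes: np.ndarray) -> set[int]:
        k = self.kmer
        if len(codes) < k:
            return set()
        valid = codes < 4
        vals = np.zeros(len(codes) - k + 1, dtype=np.int64)
        okay = np.ones(len(codes) - k + 1, dtype=bool)
        for i in range(k):
            vals = vals * 4 + codes[i : len(codes) - k + 1 + i]
            okay &= valid[i : len(codes) - k + 1 + i]
        return set(vals[okay].tolist())

    def v_candidates(self, read_codes: np.ndarray) -> list[GermlineGene]:
        if self.top_k <= 0 or self.top_k >= len(self.v_genes):
            return self.v_genes
        rk = self._kmer_set(read_codes)
        shared = np.array([len(rk & s) for s in self._v_kmers])
        order = np.argsort(-shared, kind="stable")
        return [self.v_genes[i] for i in order[: self.top_k]]


def _align_best(
    read_codes: np.ndarray,
    genes: list[GermlineGene],
    db_len: int,
    id_min: float,
    evalue_max: float,
) -> tuple[GermlineGene, LocalAlignment, float] | None:
    hits = []
    for g in genes:
        aln = smith_waterman(read_codes, g.codes)
        if aln.n_columns == 0:
            continue
        ident = aln.identity_nt(read_codes, g.codes)
        e = evalue(aln.score, len(read_codes), db_len)
        if ident >= id_min and e <= evalue_max:
            hits.append((e, -ident, g.name, g, aln))
    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    e, _, _, g, aln = hits[0]
    return g, aln, e


def _codon_columns(aln: LocalAlignment, ref_len: int) -> tuple[np.ndarray, np.ndarray]:
    """(germline codon indices, read nt starts) for codons whose three
    germline positions are aligned contiguously and in frame with the read."""
    qi, rj = aln.query_idx, aln.ref_idx
    both = (qi >= 0) & (rj >= 0)
    q, r = qi[both], rj[both]
    pos = np.full(ref_len, -1, dtype=np.int64)
    pos[r] = q
    n_codons = ref_len // 3
    p = pos[: 3 * n_codons].reshape(n_codons, 3)
    good = (p >= 0).all(axis=1) & (p[:, 1] == p[:, 0] + 1) & (p[:, 2] == p[:, 0] + 2)
    return np.flatnonzero(good), p[good, 0]


def _read_aa_frames(read_codes: np.ndarray) -> list[np.ndarray]:
    return [translate_codes(read_codes, f) for f in range(3)]


def _aa_identity(
    read_codes: np.ndarray,
    gene: GermlineGene,
    aln: LocalAlignment,
    aa_frames: list[np.ndarray] | None = None,
) -> float:
    gene_aa = translate_codes(gene.codes)
    if aa_frames is None:
        aa_frames = _read_aa_frames(read_codes)
    codons, starts = _codon_columns(aln, len(gene.codes))
    n = match = 0
    for c, q0 in zip(codons, starts):
        if c >= len(gene_aa):
            continue
        fr = aa_frames[q0 % 3]
        if q0 // 3 >= len(fr):
            continue
        n += 1
        if fr[q0 // 3] == gene_aa[c]:
            match += 1
    return 100.0 * match / n if n else 0.0


def assign_vj(
    read: Read | str,
    db: GermlineDB,
    id_min: float = DEFAULT_ID_MIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> VJAssignment | None:
    """Assign V and J by lowest-E-value local alignment; None if either
    segment has no hit passing the identity/E-value gates."""
    seq = read.seq if isinstance(read, Read) else read
    codes = encode_nt(seq)
    v_hit = _align_best(codes, db.v_candidates(codes), db.v_db_len, id_min, evalue_max)
    if v_hit is None:
        return None
    j_hit = _align_best(codes, db.j_genes, db.j_db_len, id_min, evalue_max)
    if j_hit is None:
        return None
    vg, valn, ve = v_hit
    jg, jaln, je = j_hit
    aa_frames = _read_aa_frames(codes)
    return VJAssignment(
        v_call=vg.name,
        j_call=jg.name,
        v_evalue=ve,
        j_evalue=je,
        v_identity_nt=valn.identity_nt(codes, vg.codes),
        j_identity_nt=jaln.identity_nt(codes, jg.codes),
        v_identity_aa=_aa_identity(codes, vg, valn, aa_frames),
        j_identity_aa=_aa_identity(codes, jg, jaln, aa_frames),
        v_alignment=valn,
        j_alignment=jaln,
    )


@dataclasses.dataclass
class MutationProfile:
    """Per-region mismatch tallies against the assigned germline V."""

    nt: dict[str, tuple[int, int]]  # region -> (mismatches, aligned positions)
    aa: dict[str, tuple[int, int]]
    masked_nt: int  # aligned positions excluded by the 5' primer mask
    #: IMGT positions (1-based) of codons covered / mutated at the aa level
    imgt_covered: np.ndarray
    imgt_mutated: np.ndarray


def mutation_profile(
    read: Read | str, vj: VJAssignment, gene: GermlineGene
) -> MutationProfile:
    """Tally mismatches per region at nt and (codon-aware) aa level,
    excluding germline positions inside the 5' primer mask."""
    seq = read.seq if isinstance(read, Read) else read
    codes = encode_nt(seq)
    aln = vj.v_alignment
    qi, rj = aln.query_idx, aln.ref_idx
    both = (qi >= 0) & (rj >= 0)
    q, r = qi[both], rj[both]
    mask = gene.primer_mask_nt
    masked = int((r < mask).sum())
    mismatch = codes[q] != gene.codes[r]

    nt: dict[str, tuple[int, int]] = {}
    for region in gene.region_map:
        s, e = gene.region_nt_interval(region)
        inside = (r >= max(s, mask)) & (r < e)
        nt[region] = (int(mismatch[inside].sum()), int(inside.sum()))

    gene_aa = translate_codes(gene.codes)
    aa_frames = _read_aa_frames(codes)
    cov, mut = [], []
    aa_counts = {region: [0, 0] for region in gene.region_map}
    codons, starts = _codon_columns(aln, len(gene.codes))
    for c, q0 in zip(codons, starts):
        if 3 * c < mask or c >= len(gene_aa):
            continue
        fr = aa_frames[q0 % 3]
        if q0 // 3 >= len(fr):
            continue
        imgt = gene.imgt_position_of_codon(c)
        cov.append(imgt)
        is_mut = fr[q0 // 3] != gene_aa[c]
        if is_mut:
            mut.append(imgt)
        for region, (a, b) in gene.region_map.items():
            if a <= imgt < b:
                aa_counts[region][1] += 1
                aa_counts[region][0] += int(is_mut)
                break
    aa = {region: (m, n) for region, (m, n) in aa_counts.items()}
    return MutationProfile(
        nt, aa, masked, np.array(cov, dtype=int), np.array(mut, dtype=int)
    )


@dataclasses.dataclass
class AnnotatedRead:
    """A QC-passing read with located regions, CDR3, V/J calls and mutation
    tallies; ``duplicate_count`` carries the multiplicity of identical reads."""

    read_id: str
    sequence: str
    duplicate_count: int = 1
    regions: RegionHit | None = None
    cdr3_aa: str | None = None
    vj: VJAssignment | None = None
    mutations: MutationProfile | None = None
    valid: bool = False
    fail_reason: str | None = None


@dataclasses.dataclass
class AnnotationReport:
    n_reads: int = 0
    n_unique: int = 0
    n_region_fail: int = 0
    n_cdr3_invalid: int = 0
    n_unassigned: int = 0
    n_valid: int = 0  # unique sequences fully annotated
    n_valid_reads: int = 0  # reads carried by the valid unique sequences


def annotate_reads(
    reads: list[Read],
    db: GermlineDB,
    pssm_set: PssmSet,
    id_min: float = DEFAULT_ID_MIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> tuple[list[AnnotatedRead], AnnotationReport]:
    """Annotate a sample; identical read sequences are annotated once and
    carried with their multiplicity."""
    report = AnnotationReport(n_reads=len(reads))
    by_seq: dict[str, list[Read]] = {}
    for r in reads:
        by_seq.setdefault(r.seq, []).append(r)
    report.n_unique = len(by_seq)
    out: list[AnnotatedRead] = []
    for seq, members in by_seq.items():
        ann = AnnotatedRead(members[0].id, seq, duplicate_count=len(members))
        hit = locate_regions(seq, pssm_set)
        if hit is None:
            ann.fail_reason = "region_location"
            report.n_region_fail += 1
            out.append(ann)
            continue
        ann.regions = hit
        cdr3 = extract_cdr3(hit)
        if cdr3 is None:
            ann.fail_reason = "invalid_cdr3"
            report.n_cdr3_invalid += 1
            out.append(ann)
            continue
        ann.cdr3_aa = cdr3
        vj = assign_vj(seq, db, id_min, evalue_max)
        if vj is None:
            ann.fail_reason = "unassigned"
            report.n_unassigned += 1
            out.append(ann)
            continue
        ann.vj = vj
        ann.mutations = mutation_profile(seq, vj, db.by_name[vj.v_call])
        ann.valid = True
        report.n_valid += 1
        report.n_valid_reads += len(members)
        out.append(ann)
    return out, report


def positional_mutation_profile(
    annotated: list[AnnotatedRead],
    gene: GermlineGene,
    positions: list[int] | None = None,
) -> tuple[pd.Series, float | None]:
    """Per-IMGT-position amino-acid mutation frequencies over the reads
    assigned to ``gene`` (read-weighted), plus the mean over an optional
    motif position set (e.g. the IGHV4-34 FR1 hydrophobic-patch AVY
    positions).  Empty result when no reads are assigned."""
    cov: dict[int, int] = {}
    mut: dict[int, int] = {}
    for a in annotated:
        if not a.valid or a.vj.v_call != gene.name or a.mutations is None:
            continue
        for p in a.mutations.imgt_covered:
            cov[int(p)] = cov.get(int(p), 0) + a.duplicate_count
        for p in a.mutations.imgt_mutated:
            mut[int(p)] = mut.get(int(p), 0) + a.duplicate_count
    if not cov:
        return pd.Series(dtype=float), None
    freq = pd.Series(
        {p: mut.get(p, 0) / n for p, n in sorted(cov.items())}, dtype=float
    )
    motif_mean = None
    if positions:
        vals = [freq[p] for p in positions if p in freq.index]
        motif_mean = float(np.mean(vals)) if vals else None
    return freq, motif_mean


AIRR_COLUMNS = [
    "sequence_id", "sequence", "duplicate_count", "v_call", "j_call",
    "junction_aa", "v_identity", "j_identity", "v_identity_aa",
    "j_identity_aa", "masked_nt",
]


def to_airr_table(annotated: list[AnnotatedRead]) -> pd.DataFrame:
    """AIRR-Rearrangement-style TSV table (one row per unique sequence),
    with custom per-region mutation columns."""
    rows = []
    for a in annotated:
        if not a.valid:
            continue
        row = {
            "sequence_id": a.read_id,
            "sequence": a.sequence,
            "duplicate_count": a.duplicate_count,
            "v_call": a.vj.v_call,
            "j_call": a.vj.j_call,
            "junction_aa": a.cdr3_aa,
            "v_identity": a.vj.v_identity_nt,
            "j_identity": a.vj.j_identity_nt,
            "v_identity_aa": a.vj.v_identity_aa,
            "j_identity_aa": a.vj.j_identity_aa,
            "masked_nt": a.mutations.masked_nt,
        }
        for region in ("FR1", "CDR1", "FR2", "CDR2", "FR3"):
            m, n = a.mutations.nt.get(region, (0, 0))
            row[f"region_mut_nt_{region}"] = m
            row[f"region_alnlen_nt_{region}"] = n
            m, n = a.mutations.aa.get(region, (0, 0))
            row[f"region_mut_aa_{region}"] = m
            row[f"region_alnlen_aa_{region}"] = n
        rows.append(row)
    cols = AIRR_COLUMNS + [
        f"region_{kind}_{level}_{r}"
        for r in ("FR1", "CDR1", "FR2", "CDR2", "FR3")
        for kind, level in (("mut", "nt"), ("alnlen", "nt"), ("mut", "aa"), ("alnlen", "aa"))
    ]
    return pd.DataFrame(rows, columns=cols)
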