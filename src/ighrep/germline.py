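"""Germline V/J reference handling in IMGT coordinates.

V references are stored IMGT-gapped ('.' is the gap character): each IMGT
codon position occupies exactly 3 characters of the gapped sequence, so the
standard region boundaries (FR1 = positions 1-26, CDR1 = 27-38, FR2 = 39-55,
CDR2 = 56-65, FR3 = 66-104, with the conserved Cys at 104) can be lifted onto
the ungapped sequence by counting non-gap characters.  J references are
ungapped and carry no region map; their germline identity is computed over the
whole alignment.

The first ``primer_mask_nt`` nucleotides of each V gene (default 21 nt = 7
codons) are amplification-primer binding sites and are excluded from all
mutation counting downstream.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from ._codec import decode_aa, encode_nt, translate_codes

#: IMGT half-open codon intervals for V genes (1-based IMGT positions).
REGION_MAP_V: dict[str, tuple[int, int]] = {
    "FR1": (1, 27),
    "CDR1": (27, 39),
    "FR2": (39, 56),
    "CDR2": (56, 66),
    "FR3": (66, 105),
}
V_REGIONS = tuple(REGION_MAP_V)
#: last gapped nucleotide covered by the V region map (codon 104 inclusive)
V_GAPPED_LEN = 3 * (REGION_MAP_V["FR3"][1] - 1)

DEFAULT_PRIMER_MASK_NT = 21


class GermlineError(ValueError):
    """Malformed germline reference input."""


@dataclasses.dataclass
class GermlineGene:
    """One germline V or J allele.

    Parameters
    ----------
    name
        Allele identifier, e.g. ``"IGHV4-34*01"``.
    segment
        ``"V"`` or ``"J"``.
    seq_gapped
        Nucleotide sequence over ``{A,C,G,T,.}`` in IMGT gapped coordinates
        (for J genes this equals ``seq``).
    primer_mask_nt
        Number of 5' nucleotides excluded from mutation counting (V only).
    """

    name: str
    segment: str
    seq_gapped: str
    primer_mask_nt: int = DEFAULT_PRIMER_MASK_NT

    def __post_init__(self) -> None:
        if self.segment not in ("V", "J"):
            raise GermlineError(f"segment must be 'V' or 'J', got {self.segment!r}")
        bad = set(self.seq_gapped) - set("ACGT.")
        if bad:
            raise GermlineError(
                f"record {self.name!r}: invalid characters {sorted(bad)} "
                "(expected A/C/G/T and '.' gaps)"
            )
        self.seq: str = self.seq_gapped.replace(".", "")
        if self.segment == "V":
            if len(self.seq_gapped) < V_GAPPED_LEN:
                raise GermlineError(
                    f"record {self.name!r}: gapped V sequence of "
                    f"{len(self.seq_gapped)} nt does not reach the FR3 end "
                    f"({V_GAPPED_LEN} nt in IMGT coordinates)"
                )
            self.region_map: dict[str, tuple[int, int]] = dict(REGION_MAP_V)
        else:
            self.region_map = {}
        if self.primer_mask_nt % 3 != 0 or not 0 <= self.primer_mask_nt <= len(self.seq):
            raise GermlineError(
                f"record {self.name!r}: primer_mask_nt must be a non-negative "
                "multiple of 3 no longer than the sequence"
            )
        # map ungapped position -> gapped position, and per-codon IMGT numbers
        g = np.frombuffer(self.seq_gapped.encode(), dtype=np.uint8)
        self._ungapped_to_gapped = np.flatnonzero(g != ord("."))
        self.codes: np.ndarray = encode_nt(self.seq)

    # -- coordinates ----------------------------------------------------

    def gapped_to_ungapped_nt(self, gapped_pos: int) -> int:
        """Number of non-gap nucleotides strictly before ``gapped_pos``."""
        return int(np.searchsorted(self._ungapped_to_gapped, gapped_pos))

    def region_nt_interval(self, region: str) -> tuple[int, int]:
        """Half-open 0-based nucleotide interval of ``region`` on the
        ungapped sequence (gap-aware)."""
        if region not in self.region_map:
            raise GermlineError(
                f"region {region!r} not defined for {self.segment} gene {self.name}"
            )
        a, b = self.region_map[region]
        return (
            self.gapped_to_ungapped_nt(3 * (a - 1)),
            self.gapped_to_ungapped_nt(3 * (b - 1)),
        )

    @property
    def v_nt_len(self) -> int:
        """Ungapped length of the region-mapped V portion (through Cys104)."""
        return self.gapped_to_ungapped_nt(V_GAPPED_LEN)

    def imgt_position_of_codon(self, ungapped_codon: int) -> int:
        """IMGT (1-based) position of an ungapped codon index."""
        return self._ungapped_to_gapped[3 * ungapped_codon] // 3 + 1

    def aa(self) -> str:
        """Translation of the ungapped sequence (frame 0)."""
        return decode_aa(translate_codes(self.codes))

    def region_aa_interval_ungapped(self, region: str) -> tuple[int, int]:
        """Region interval in ungapped amino-acid (codon) coordinates."""
        s, e = self.region_nt_interval(region)
        return s // 3, e // 3


def codon_interval_to_nt(gene: GermlineGene, region: str) -> tuple[int, int]:
    """Nucleotide interval of an IMGT region on the ungapped sequence."""
    return gene.region_nt_interval(region)


# -- FASTA I/O ----------------------------------------------------------


def _allele_name(header: str) -> str:
    """IMGT headers are pipe-delimited with the allele in field 2; plain
    headers are used whole."""
    fields = header.split("|")
    if len(fields) > 1:
        return fields[1].strip() or fields[0].strip()
    return header.strip()


def read_imgt_fasta(
    path: str | Path,
    segment: str,
    primer_mask_nt: int = DEFAULT_PRIMER_MASK_NT,
) -> list[GermlineGene]:
    """Read germline genes from an (optionally IMGT-gapped) FASTA file.

    Raises :class:`GermlineError` on an empty file, duplicate allele names,
    or invalid sequence characters.
    """
    path = Path(path)
    genes: list[GermlineGene] = []
    seen: set[str] = set()
    name = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if name in seen:
            raise GermlineError(f"duplicate allele name {name!r} in {path}")
        seen.add(name)
        genes.append(
            GermlineGene(
                name,
                segment,
                seq,
                primer_mask_nt=primer_mask_nt if segment == "V" else 0,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = _allele_name(line[1:])
                chunks = []
            else:
                chunks.append(line)
    flush()
    if not genes:
        raise GermlineError(f"no FASTA records in {path}")
    return genes


def write_imgt_fasta(genes: Iterable[GermlineGene], path: str | Path) -> None:
    """Write genes back to FASTA (gapped sequence, bare allele headers)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.name}\n{g.seq_gapped}\n")


def gene_name(allele: str) -> str:
    """Collapse an allele name to the gene level (truncate at '*')."""
    return allele.split("*")[0]


# -- synthetic reference set -------------------------------------------

_SYNTH_V_NAMES = [
    "IGHV1-2*01",
    "IGHV2-70*01",
    "IGHV3-23*01",
    "IGHV4-30-2*01",
    "IGHV4-31*01",
    "IGHV4-34*01",
    "IGHV5-51*01",
    "IGHV6-1*01",
]
_SYNTH_J = {
    # name -> (CDR3-tail aa, FR4 aa starting at the conserved Trp)
    "IGHJ3*01": ("AFDI", "WGQGTMVTVSS"),
    "IGHJ4*01": ("YFDY", "WGQGTLVTVSS"),
    "IGHJ5*01": ("NWFDS", "WGRGTLVTVSS"),
    "IGHJ6*01": ("YYGMDV", "WGKGTTVTVSS"),
}

_STOPS = {"TAA", "TAG", "TGA"}


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in _STOPS:
            return c


def _mutate_codon(codon: str, rng: np.random.Generator, rate: float) -> str:
    for _ in range(20):
        out = []
        for b in codon:
            if rng.random() < rate:
                b = rng.choice([x for x in "ACGT" if x != b])
            out.append(b)
        cand = "".join(out)
        if cand not in _STOPS:
            return cand
    return codon


def _aa_to_nt(aa: str, rng: np.random.Generator) -> str:
    """Pick a codon per residue (first matching codon table entry, jittered
    at the wobble position when synonymous)."""
    from Bio.Data.CodonTable import standard_dna_table

    by_aa: dict[str, list[str]] = {}
    for codon, res in standard_dna_table.forward_table.items():
        by_aa.setdefault(res, []).append(codon)
    return "".join(str(rng.choice(by_aa[res])) for res in aa)


def synthetic_germline_set(
    seed: int = 2024,
) -> tuple[list[GermlineGene], list[GermlineGene]]:
    """Deterministically generate the synthetic germline reference bundle.

    Eight V genes (IMGT-gapped, pairwise < 85% nucleotide identity, with the
    conserved Cys23/Trp41/Cys104 framework anchors and gene-specific CDR1/CDR2
    lengths realised as IMGT gaps) and four J genes.  This is a synthetic
    stand-in for an IMGT reference release, shaped like one; real IMGT files
    are read through the same :func:`read_imgt_fasta`.
    """
    rng = np.random.default_rng(seed)
    # base codon backbone over the 104 IMGT positions
    base = [_random_codon(rng) for _ in range(104)]
    anchors = {22: "TGC", 40: "TGG", 103: "TGT"}  # 0-based IMGT-1: C23, W41, C104
    for pos, codon in anchors.items():
        base[pos] = codon

    cdr1_len = {n: int(rng.choice([8, 10, 12])) for n in _SYNTH_V_NAMES}
    cdr2_len = {n: int(rng.choice([7, 8, 10])) for n in _SYNTH_V_NAMES}

    v_genes = []
    for vname in _SYNTH_V_NAMES:
        codons = []
        for i, c in enumerate(base):
            if i in anchors:
                codons.append(anchors[i])
            else:
                rate = 0.18 if (26 <= i < 38 or 55 <= i < 65) else 0.10
                codons.append(_mutate_codon(c, rng, rate))
        # carve gaps: keep the first k codons of each CDR, gap the rest
        c1a, c1b = 26, 38  # 0-based codon indices of CDR1
        c2a, c2b = 55, 65
        for start, end, keep in ((c1a, c1b, cdr1_len[vname]), (c2a, c2b, cdr2_len[vname])):
            for i in range(start + keep, end):
                codons[i] = "..."
        v_genes.append(GermlineGene(vname, "V", "".join(codons)))

    j_genes = []
    for jname, (tail, fr4) in _SYNTH_J.items():
        j_genes.append(GermlineGene(jname, "J", _aa_to_nt(tail + fr4, rng), 0))
    return v_genes, j_genes


def builtin_germlines() -> tuple[list[GermlineGene], list[GermlineGene]]:
    """Load the bundled synthetic V/J reference FASTA files."""
    data = resources.files("ighrep") / "data"
    with resources.as_file(data / "synthetic_v.fasta") as p:
        v = read_imgt_fasta(p, "V")
    with resources.as_file(data / "synthetic_j.fasta") as p:
        j = read_imgt_fasta(p, "J")
    return v, j


def j_anchor_codon(gene: GermlineGene) -> int:
    """0-based codon index of the conserved FR4 Trp (WGxG motif) in a J gene."""
    aa = gene.aa()
    for i in range(len(aa) - 3):
        if aa[i] == "W" and aa[i + 1] == "G" and aa[i + 3] == "G":
            return i
    raise GermlineError(f"J gene {gene.name}: no WGxG motif found")
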