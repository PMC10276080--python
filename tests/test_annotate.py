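import numpy as np
import pytest

from ighrep._codec import AA_STOP, encode_aa, translate
from ighrep.annotate import (
    GermlineDB,
    _log_odds,
    annotate_reads,
    assign_vj,
    build_junction_pssms,
    extract_cdr3,
    locate_regions,
    mutation_profile,
    positional_mutation_profile,
    to_airr_table,
)
from ighrep.qc import Read
from conftest import make_clones


def expected_boundaries(gene, cdr3_len):
    """Frame-0 junction positions implied by the germline region map."""
    b = [gene.region_aa_interval_ungapped(r)[1] for r in ("FR1", "CDR1", "FR2", "CDR2")]
    b5 = gene.v_nt_len // 3
    return b + [b5, b5 - 1 + cdr3_len]


def _as_reads(clones):
    return [Read(f"r{i}", c.sequence, np.full(len(c.sequence), 40)) for i, c in enumerate(clones)]


def _replace_codon(seq, codon_idx, new):
    return seq[: 3 * codon_idx] + new + seq[3 * codon_idx + 3 :]


class TestPssmConstruction:
    def test_single_reference_matrix_peaks_at_its_residues(self, v_genes, j_genes):
        ps = build_junction_pssms(v_genes[:1], j_genes[:1])
        g = v_genes[0]
        from ighrep._codec import translate_codes

        aa = translate_codes(g.codes)
        for junction in ("FR1/CDR1", "CDR1/FR2", "FR2/CDR2", "CDR2/FR3"):
            p = ps.pssms[junction]
            b = g.region_aa_interval_ungapped(junction.split("/")[0])[1]
            window = aa[b - p.window_left : b + p.window_right]
            assert (p.matrix.argmax(axis=1) == window).all()
            # the training window attains the maximal achievable score
            assert p.score_window(aa, b) == pytest.approx(p.matrix.max(axis=1).sum())

    def test_training_windows_clear_their_own_threshold(self, v_genes, pssms):
        from ighrep._codec import translate_codes

        for junction in ("FR1/CDR1", "CDR1/FR2", "FR2/CDR2", "CDR2/FR3"):
            p = pssms.pssms[junction]
            scores = []
            for g in v_genes:
                b = g.region_aa_interval_ungapped(junction.split("/")[0])[1]
                scores.append(p.score_window(translate_codes(g.codes), b))
            assert np.mean(scores) >= p.min_score

    def test_window_shrinks_with_warning_on_short_reference(self, v_genes):
        from ighrep.germline import GermlineGene

        stub_j = GermlineGene("Jstub", "J", "TACTGGGGCCAAGGC", 0)  # YWGQG
        with pytest.warns(UserWarning, match="shrunk"):
            ps = build_junction_pssms(v_genes, [stub_j])
        p = ps.pssms["CDR3/FR4"]
        assert p.window_left + p.window_right < 10

    def test_uniform_column_counts_give_equal_scores(self):
        # one window per amino acid -> every residue seen once per column
        windows = [encode_aa(aa) for aa in "ACDEFGHIKLMNPQRSTVWY"]
        mat = _log_odds(windows, 1, 1.0, np.full(22, 1 / 20))
        assert np.allclose(mat[0, :20], mat[0, 0])


class TestLocateRegions:
    def test_unmutated_reads_hit_truth_boundaries_exactly(self, clean_clones, pssms, v_genes):
        by_name = {g.name: g for g in v_genes}
        for c in clean_clones[:100]:
            hit = locate_regions(c.sequence, pssms)
            assert hit is not None and hit.frame == 0
            exp = expected_boundaries(by_name[c.v_call], len(c.cdr3_aa))
            got = [hit.boundaries[j] for j in
                   ("FR1/CDR1", "CDR1/FR2", "FR2/CDR2", "CDR2/FR3", "FR3/CDR3", "CDR3/FR4")]
            assert got == exp

    def test_random_sequences_fail(self, pssms):
        rng = np.random.default_rng(21)
        fails = sum(
            locate_regions("".join(rng.choice(list("ACGT"), 390)), pssms) is None
            for _ in range(100)
        )
        assert fails >= 99

    def test_stop_codon_in_fr3_fails(self, clean_clones, pssms, v_genes):
        c = clean_clones[0]
        gene = next(g for g in v_genes if g.name == c.v_call)
        s, _ = gene.region_nt_interval("FR3")
        broken = _replace_codon(c.sequence, s // 3 + 2, "TAA")
        assert translate(broken)[s // 3 + 2] == "*"
        assert locate_regions(broken, pssms) is None


class TestExtractCdr3:
    def test_recovers_simulated_truth(self, clean_clones, pssms):
        for c in clean_clones[:50]:
            hit = locate_regions(c.sequence, pssms)
            assert extract_cdr3(hit) == c.cdr3_aa

    def test_stop_in_cdr3_is_invalid(self, clean_clones, pssms):
        hit = locate_regions(clean_clones[0].sequence, pssms)
        s, e = hit.region_aa["CDR3"]
        hit.aa_codes[(s + e) // 2] = AA_STOP
        assert extract_cdr3(hit) is None

    def test_cdr3_below_five_aa_is_invalid(self, clean_clones, pssms):
        hit = locate_regions(clean_clones[0].sequence, pssms)
        s, e = hit.region_aa["CDR3"]
        hit.region_aa["CDR3"] = (s, s + 4)
        assert extract_cdr3(hit) is None


class TestAssignVj:
    def test_unmutated_read_gets_its_gene_at_full_identity(self, clean_clones, db):
        for c in clean_clones[:30]:
            vj = assign_vj(c.sequence, db)
            assert vj is not None
            assert vj.v_call == c.v_call and vj.j_call == c.j_call
            assert vj.v_identity_nt == 100.0
            assert vj.v_identity_aa == 100.0
            assert vj.v_evalue <= 1e-3

    def test_three_substitutions_give_ninety_nine_percent(self, clean_clones, db, v_genes):
        gene = next(g for g in v_genes if g.v_nt_len == 300)
        c = next(c for c in clean_clones if c.v_call == gene.name)
        seq = list(c.sequence)
        for pos in (50, 150, 250):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        vj = assign_vj("".join(seq), db)
        assert vj.v_call == gene.name
        assert vj.v_identity_nt == pytest.approx(99.0)

    def test_read_matches_its_own_gene_not_a_neighbour(self, clean_clones, v_genes, j_genes):
        exhaustive = GermlineDB(v_genes, j_genes, top_k=0)
        for c in clean_clones[:30]:
            vj = assign_vj(c.sequence, exhaustive)
            assert vj.v_call == c.v_call

    def test_prefilter_agrees_with_exhaustive_search(self, v_genes, j_genes):
        clones = make_clones(v_genes, j_genes, 0.05, 40, seed=77)
        fast = GermlineDB(v_genes, j_genes, top_k=3)
        full = GermlineDB(v_genes, j_genes, top_k=0)
        for c in clones:
            a, b = assign_vj(c.sequence, fast), assign_vj(c.sequence, full)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.v_call == b.v_call and a.j_call == b.j_call

    def test_garbage_read_unassigned(self, db):
        rng = np.random.default_rng(3)
        assert assign_vj("".join(rng.choice(list("ACGT"), 200)), db) is None


class TestMutationProfile:
    def test_unmutated_read_has_zero_frequencies(self, clean_clones, db, v_genes):
        c = clean_clones[0]
        vj = assign_vj(c.sequence, db)
        prof = mutation_profile(c.sequence, vj, db.by_name[vj.v_call])
        for region, (m, n) in prof.nt.items():
            assert m == 0 and n > 0
        assert len(prof.imgt_mutated) == 0

    def test_substitution_inside_primer_mask_is_not_counted(self, clean_clones, db):
        c = clean_clones[0]
        seq = list(c.sequence)
        seq[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[10]]
        seq = "".join(seq)
        vj = assign_vj(seq, db)
        prof = mutation_profile(seq, vj, db.by_name[vj.v_call])
        assert sum(m for m, _ in prof.nt.values()) == 0
        assert prof.masked_nt >= 21

    def test_two_substitutions_in_one_fr3_codon_count_once_at_aa_level(
        self, clean_clones, db, v_genes
    ):
        c = clean_clones[0]
        gene = db.by_name[c.v_call]
        s, e = gene.region_nt_interval("FR3")
        cs = (s // 3 + 3) * 3  # a codon well inside FR3
        codon = c.sequence[cs : cs + 3]
        new = "GCT" if translate(codon) != "A" else "GGT"
        seq = _replace_codon(c.sequence, cs // 3, new)
        nt_diff = sum(a != b for a, b in zip(codon, new))
        assert nt_diff >= 2
        vj = assign_vj(seq, db)
        prof = mutation_profile(seq, vj, gene)
        assert prof.nt["FR3"][0] == nt_diff
        assert prof.aa["FR3"][0] == 1

    def test_region_tallies_conserve_aligned_columns(self, v_genes, j_genes, db):
        clones = make_clones(v_genes, j_genes, 0.03, 30, seed=55)
        for c in clones:
            vj = assign_vj(c.sequence, db)
            if vj is None:
                continue
            gene = db.by_name[vj.v_call]
            prof = mutation_profile(c.sequence, vj, gene)
            aln = vj.v_alignment
            both = (aln.query_idx >= 0) & (aln.ref_idx >= 0)
            in_v = both & (aln.ref_idx < gene.v_nt_len)
            assert prof.masked_nt + sum(n for _, n in prof.nt.values()) == in_v.sum()


@pytest.fixture(scope="module")
def planted(v_genes, j_genes, db, pssms, clean_clones):
    gene = next(g for g in v_genes if g.name == "IGHV4-34*01")
    base = next(c for c in clean_clones if c.v_call == gene.name)
    positions = (30, 40, 60)  # IMGT positions past the primer mask
    variants = []
    for p in positions:
        codon = base.sequence[3 * (p - 1) : 3 * (p - 1) + 3]
        new = "GCT" if translate(codon) != "A" else "GGT"
        variants.append(_replace_codon(base.sequence, p - 1, new))
    reads = []
    for seq, n in zip([*variants, base.sequence], (5, 10, 15, 20)):
        reads += [Read(f"x{len(reads)}_{k}", seq, np.full(len(seq), 40)) for k in range(n)]
    annotated, _ = annotate_reads(reads, db, pssms)
    return gene, positions, annotated


class TestPositionalProfile:
    def test_zero_shm_gives_all_zero(self, clean_clones, db, pssms, v_genes):
        gene = next(g for g in v_genes if g.name == clean_clones[0].v_call)
        reads = _as_reads([c for c in clean_clones[:40] if c.v_call == gene.name])
        annotated, _ = annotate_reads(reads, db, pssms)
        freq, _ = positional_mutation_profile(annotated, gene)
        assert (freq == 0).all()

    def test_planted_fraction_recovered(self, planted):
        gene, positions, annotated = planted
        freq, _ = positional_mutation_profile(annotated, gene)
        assert freq[positions[0]] == pytest.approx(5 / 50)
        assert freq[positions[1]] == pytest.approx(10 / 50)
        assert freq[positions[2]] == pytest.approx(15 / 50)

    def test_motif_mean_over_positions(self, planted):
        gene, positions, annotated = planted
        _, motif = positional_mutation_profile(annotated, gene, list(positions))
        assert motif == pytest.approx(np.mean([0.1, 0.2, 0.3]))

    def test_gene_without_reads_gives_empty(self, v_genes):
        freq, motif = positional_mutation_profile([], v_genes[0], [25])
        assert freq.empty and motif is None


class TestAnnotateReads:
    def test_dedup_and_airr_table(self, clean_clones, db, pssms):
        reads = _as_reads(clean_clones[:20]) + _as_reads(clean_clones[:5])
        annotated, report = annotate_reads(reads, db, pssms)
        assert report.n_reads == 25 and report.n_unique == 20
        assert report.n_valid_reads == 25
        t = to_airr_table(annotated)
        assert t["duplicate_count"].sum() == 25
        assert set(t["v_call"]) <= {c.v_call for c in clean_clones[:20]}
        assert (t["v_identity"] == 100.0).all()
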