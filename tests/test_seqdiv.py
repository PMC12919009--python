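"""Divergence counting: JC correction, p-distances, difference matrices, NG86."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoclock.seqdiv import (
    AlignmentError,
    CodonAlignment,
    SaturationError,
    jc_p_from_d,
    jukes_cantor,
    ng86_kaks,
    pairwise_difference_matrix,
    read_codon_fasta,
    third_position_p_distance,
)

from conftest import mutate_sites, random_codon_seq


class TestCodonAlignment:
    def test_identical_records_roundtrip(self, tmp_path):
        fp = tmp_path / "two.fasta"
        fp.write_text(">a\nATGAAATTT\n>b\nATGAAATTT\n")
        aln = read_codon_fasta(fp)
        assert aln.length == 9
        assert aln.taxa == ("a", "b")
        assert aln.n_codons == 3

    def test_unequal_lengths_rejected(self, tmp_path):
        fp = tmp_path / "bad.fasta"
        fp.write_text(">a\nATGAAATTT\n>b\nATGAAATTTCCC\n")
        with pytest.raises(AlignmentError, match="unequal"):
            read_codon_fasta(fp)

    def test_illegal_character_names_taxon_and_position(self, tmp_path):
        fp = tmp_path / "bad.fasta"
        fp.write_text(">a\nATGAAATTT\n>b\nATGAXATTT\n")
        with pytest.raises(AlignmentError, match=r"'b'.*position 4"):
            read_codon_fasta(fp)

    def test_synthetic_locus_has_166_codons(self, tmp_path, rng):
        seq = random_codon_seq(rng, 166)
        recs = "".join(f">t{i}\n{seq}\n" for i in range(7))
        fp = tmp_path / "locus.fasta"
        fp.write_text(recs)
        aln = read_codon_fasta(fp)
        assert aln.length == 498
        assert aln.n_codons == 166
        assert len(aln.taxa) == 7

    def test_frameshift_rejected(self):
        with pytest.raises(AlignmentError, match="multiple of 3"):
            CodonAlignment(taxa=("a",), sequences={"a": "ATGA"})


class TestJukesCantor:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, 0.0), (0.113, 0.1224776632), (0.5, -0.75 * math.log(1 / 3))],
    )
    def test_closed_form(self, p, expected):
        assert jukes_cantor(p) == pytest.approx(expected, rel=1e-9)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    @given(st.floats(min_value=0.0, max_value=2.0))
    @settings(max_examples=200, deadline=None)
    def test_exact_inverse_of_p_of_d(self, d):
        assert jukes_cantor(jc_p_from_d(d)) == pytest.approx(d, abs=1e-12)

    def test_monotone(self):
        grid = np.linspace(0, 0.74, 200)
        vals = [jukes_cantor(p) for p in grid]
        assert np.all(np.diff(vals) > 0)
        assert all(v >= p for v, p in zip(vals, grid))


class TestThirdPositionDistance:
    def test_identical_sequences(self):
        aln = CodonAlignment(
            taxa=("a", "b"), sequences={"a": "ATGAAA", "b": "ATGAAA"}
        )
        est = third_position_p_distance(aln, "a", "b")
        assert est.p == 0.0 and est.d == 0.0 and est.n_sites == 2

    def test_symmetry_and_reordering_invariance(self, rng):
        a = random_codon_seq(rng, 50)
        b = mutate_sites(a, list(rng.choice(150, size=20, replace=False)), rng)
        c = mutate_sites(a, list(rng.choice(150, size=10, replace=False)), rng)
        aln1 = CodonAlignment(taxa=("a", "b", "c"),
                              sequences={"a": a, "b": b, "c": c})
        aln2 = CodonAlignment(taxa=("c", "b", "a"),
                              sequences={"a": a, "b": b, "c": c})
        e1 = third_position_p_distance(aln1, "a", "b")
        e2 = third_position_p_distance(aln1, "b", "a")
        e3 = third_position_p_distance(aln2, "a", "b")
        assert e1 == e2 == e3

    def test_matches_brute_force_site_counter(self, rng):
        a = random_codon_seq(rng, 300)
        b = mutate_sites(a, list(rng.choice(900, size=90, replace=False)), rng)
        aln = CodonAlignment(taxa=("a", "b"), sequences={"a": a, "b": b})
        est = third_position_p_distance(aln, "a", "b")
        # brute force: explicit loop over third positions
        diffs = comp = 0
        for i in range(2, 900, 3):
            if a[i] in "ACGT" and b[i] in "ACGT":
                comp += 1
                diffs += a[i] != b[i]
        assert est.n_sites == comp == 300
        assert est.p == pytest.approx(diffs / comp)

    def test_pairwise_deletion_of_missing_sites(self):
        aln = CodonAlignment(
            taxa=("a", "b"), sequences={"a": "ATGAANATT", "b": "ATGAATAT-"}
        )
        est = third_position_p_distance(aln, "a", "b")
        assert est.n_sites == 1  # only the first codon's third site comparable
        assert est.p == 0.0

    def test_no_comparable_sites_errors(self):
        aln = CodonAlignment(taxa=("a", "b"),
                             sequences={"a": "ATN", "b": "AT-"})
        with pytest.raises(AlignmentError, match="no comparable"):
            third_position_p_distance(aln, "a", "b")

    def test_jc_mean_recovers_simulated_depth(self):
        # sequences simulated under JC at total depth d: mean of corrected
        # estimates over replicates within 3 SE of truth
        from endoclock.synthetic_data import evolve_jc

        rng = np.random.default_rng(7)
        d = 0.25
        n_sites, n_rep = 10_000, 200
        ests = np.empty(n_rep)
        for r in range(n_rep):
            anc = rng.integers(0, 4, size=n_sites)
            der = evolve_jc(anc, d, rng)
            p = float((anc != der).mean())
            ests[r] = jukes_cantor(p)
        se = ests.std(ddof=1) / math.sqrt(n_rep)
        assert abs(ests.mean() - d) < 3 * se


class TestPairwiseDifferenceMatrix:
    def test_identical_alleles_zero_matrix(self):
        seq = "ATGAAATTT"
        aln = CodonAlignment(
            taxa=("a", "b", "c"), sequences={t: seq for t in "abc"}
        )
        assert not pairwise_difference_matrix(aln).to_numpy().any()

    def test_matches_brute_force_recount(self, rng):
        seqs = {}
        base = random_codon_seq(rng, 40)
        for t in "abcd":
            seqs[t] = mutate_sites(
                base, list(rng.choice(120, size=15, replace=False)), rng
            )
        aln = CodonAlignment(taxa=tuple("abcd"), sequences=seqs)
        mat = pairwise_difference_matrix(aln)
        for i in "abcd":
            for j in "abcd":
                brute = sum(
                    1
                    for x, y in zip(seqs[i], seqs[j])
                    if x in "ACGT" and y in "ACGT" and x != y
                )
                assert mat.loc[i, j] == brute
        assert (mat.to_numpy() == mat.to_numpy().T).all()

    def test_outlier_allele_pattern(self, rng):
        # one allele far from a tight background, emulating a horizontally
        # acquired allele at a 1,282-bp locus
        base = random_codon_seq(rng, 428)[:1281]
        base += "A" * (1284 - len(base))  # pad to multiple of 3
        taxa = [f"t{i}" for i in range(20)]
        seqs = {t: base for t in taxa}
        seqs["t0"] = mutate_sites(
            base, list(rng.choice(len(base), size=36, replace=False)), rng
        )
        for t in taxa[1:6]:
            seqs[t] = mutate_sites(base, [int(rng.integers(0, len(base)))], rng)
        aln = CodonAlignment(taxa=tuple(taxa), sequences=seqs)
        mat = pairwise_difference_matrix(aln)
        others = taxa[1:]
        assert mat.loc["t0", others].min() >= 30
        assert mat.loc[others, others].to_numpy().max() <= 5


class TestNg86:
    def test_identical_sequences_omega_undefined(self, rng):
        a = random_codon_seq(rng, 50)
        aln = CodonAlignment(taxa=("x", "y"), sequences={"x": a, "y": a})
        est = ng86_kaks(aln, "x", "y")
        assert est.Ka == est.Ks == 0.0
        assert est.omega is None

    def test_single_synonymous_change(self):
        a = "TTT" + "AAA" * 99
        b = "TTC" + "AAA" * 99
        aln = CodonAlignment(taxa=("x", "y"), sequences={"x": a, "y": b})
        est = ng86_kaks(aln, "x", "y")
        assert est.Ka == 0.0
        assert est.Ks > 0.0

    def test_site_counts_sum_to_three_per_codon(self, pair_alignment):
        est = ng86_kaks(pair_alignment, "x", "y")
        assert est.n_syn_sites + est.n_nonsyn_sites == pytest.approx(
            3 * est.n_codons
        )

    def test_matches_independent_ng86_implementation(self, pair_alignment):
        # Biopython's NG86 (pathway enumeration + JC correction) as oracle
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        est = ng86_kaks(pair_alignment, "x", "y")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(
                CodonSeq(pair_alignment.sequence("x")),
                CodonSeq(pair_alignment.sequence("y")),
                method="NG86",
            )
        assert est.Ka == pytest.approx(dn, abs=1e-9)
        assert est.Ks == pytest.approx(ds, abs=1e-9)

    def test_pathway_counts_by_exhaustive_enumeration(self):
        # brute-force check of the two-step pathway average for one codon
        # pair: TTT (F) -> GTC (V) via GTT(V)/TTC(F): path1 = N,S; path2 = S,N
        from endoclock.seqdiv import _pathway_counts

        sd, nd = _pathway_counts("TTT", "GTC")
        assert (sd, nd) == (1.0, 1.0)
        # CCT (P) -> CAA (Q): via CAT (H) = N,N ; via CCA (P) = S,N
        sd, nd = _pathway_counts("CCT", "CAA")
        assert (sd, nd) == (0.5, 1.5)

    def test_synonymous_only_changes_give_zero_ka(self, rng):
        # implant only third-position synonymous changes in 4-fold codons
        fourfold = ["CTT", "GTT", "TCT", "CCT", "ACT", "GCT", "CGT", "GGT"]
        a = "".join(fourfold[i] for i in rng.integers(0, 8, size=120))
        b = list(a)
        for c in range(0, 120, 3):
            b[3 * c + 2] = {"T": "C", "C": "T"}[b[3 * c + 2]] if b[
                3 * c + 2
            ] in "TC" else b[3 * c + 2]
        aln = CodonAlignment(taxa=("x", "y"),
                             sequences={"x": a, "y": "".join(b)})
        est = ng86_kaks(aln, "x", "y")
        assert est.Ka == 0.0
        assert est.Ks > 0.0

    def test_stop_codons_skipped_with_warning(self):
        a = "TAA" + "AAA" * 10
        b = "TAC" + "AAA" * 10
        aln = CodonAlignment(taxa=("x", "y"), sequences={"x": a, "y": b})
        with pytest.warns(UserWarning, match="stop codon"):
            est = ng86_kaks(aln, "x", "y")
        assert est.n_codons == 10
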