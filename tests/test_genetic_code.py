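"""Codon counting, RSCU, CAI and Fop against hand and brute-force oracles."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import codonopt as co
from codonopt.genetic_code import (
    AmbiguousNucleotideError,
    InternalStopError,
    InvalidSequenceError,
)


def brute_rscu(counts, table):
    """Independent RSCU oracle: degeneracy * count / family total."""
    out = {}
    for aa, codons in table.aa_to_codons.items():
        tot = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = math.nan if tot == 0 else len(codons) * counts.get(c, 0) / tot
    return out


class TestCodingSequence:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGGGAGGA", {"ATG": 1, "GGA": 2}),
            ("ATGTAA", {"ATG": 1}),  # terminal stop dropped
            ("GGAGGAGGC", {"GGA": 2, "GGC": 1}),
        ],
    )
    def test_count_codons(self, seq, expected):
        cds = co.CodingSequence.from_sequence("g", seq)
        assert dict(co.count_codons(cds).counts) == expected

    def test_internal_stop_rejected(self):
        with pytest.raises(InternalStopError):
            co.CodingSequence.from_sequence("g", "ATGTAAGGA")

    def test_bad_length_rejected(self):
        with pytest.raises(InvalidSequenceError):
            co.CodingSequence.from_sequence("g", "ATGG")

    def test_ambiguous_rejected(self):
        with pytest.raises(AmbiguousNucleotideError):
            co.CodingSequence.from_sequence("g", "ATGNNN")

    def test_counts_additive_over_concatenation(self, code):
        a = co.CodingSequence.from_sequence("a", "ATGGGATTC")
        b = co.CodingSequence.from_sequence("b", "GGAGGCAAG")
        merged = co.concatenate_counts([a, b])
        summed = Counter(co.count_codons(a).counts) + Counter(co.count_codons(b).counts)
        assert dict(merged.counts) == dict(summed)


class TestRSCU:
    def test_uniform_use_gives_ones(self, code):
        counts = co.CodonCounts({c: 10 for c in code.aa_to_codons["G"]})
        profile = co.rscu(counts)
        assert all(profile[c] == pytest.approx(1.0) for c in code.aa_to_codons["G"])

    def test_hand_oracle_glycine(self):
        counts = co.CodonCounts({"GGA": 3, "GGC": 1, "GGG": 0, "GGT": 0})
        profile = co.rscu(counts)
        assert profile["GGA"] == pytest.approx(3.0)
        assert profile["GGC"] == pytest.approx(1.0)
        assert profile["GGG"] == 0 and profile["GGT"] == 0

    def test_absent_amino_acid_is_nan(self, code):
        profile = co.rscu(co.CodonCounts({"GGA": 5}))
        assert all(math.isnan(profile[c]) for c in code.aa_to_codons["C"])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rscu_sums_to_degeneracy_on_random_counts(self, seed):
        code = co.STANDARD_CODE
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 40)) for c in code.degenerate_codons}
        profile = co.rscu(co.CodonCounts(counts))
        for aa in code.degenerate_aas:
            codons = code.aa_to_codons[aa]
            if sum(counts.get(c, 0) for c in codons) > 0:
                assert sum(profile[c] for c in codons) == pytest.approx(
                    code.degeneracy[aa], abs=1e-9
                )

    def test_scale_invariance(self, code):
        rng = np.random.default_rng(0)
        counts = {c: int(rng.integers(1, 30)) for c in code.degenerate_codons}
        p1 = co.rscu(co.CodonCounts(counts))
        p2 = co.rscu(co.CodonCounts({c: 7 * n for c, n in counts.items()}))
        for c in code.degenerate_codons:
            assert p1[c] == pytest.approx(p2[c], abs=1e-12)

    def test_matches_brute_force(self, code):
        rng = np.random.default_rng(5)
        counts = {c: int(rng.integers(0, 20)) for c in code.degenerate_codons}
        profile = co.rscu(co.CodonCounts(counts))
        oracle = brute_rscu(counts, code)
        for c in code.degenerate_codons:
            assert profile[c] == pytest.approx(oracle[c], abs=1e-9, nan_ok=True)


class TestCAI:
    def test_max_codon_gets_weight_one(self, code):
        counts = {c: 1 for c in code.degenerate_codons}
        counts["GGC"] = 50
        w = co.cai_weights(co.CodonCounts(counts))
        assert w.w["GGC"] == pytest.approx(1.0)
        for aa in code.degenerate_aas:
            assert max(w.w[c] for c in code.aa_to_codons[aa]) == pytest.approx(1.0)

    def test_two_fold_ratio(self):
        # RSCU pair (1.6, 0.4) -> weights (1.0, 0.25)
        counts = {c: 1 for c in co.STANDARD_CODE.degenerate_codons}
        counts["TTC"], counts["TTT"] = 8, 2
        w = co.cai_weights(co.CodonCounts(counts))
        assert w.w["TTC"] == pytest.approx(1.0)
        assert w.w["TTT"] == pytest.approx(0.25)

    def test_zero_count_gets_floor(self, code):
        counts = {c: 1 for c in code.degenerate_codons}
        counts["GGG"] = 0
        w = co.cai_weights(co.CodonCounts(counts))
        assert w.w["GGG"] == pytest.approx(0.01)

    def test_missing_amino_acid_errors(self, code):
        counts = {c: 1 for c in code.degenerate_codons if code.codon_to_aa[c] != "C"}
        with pytest.raises(co.genetic_code.ReferenceCoverageError):
            co.cai_weights(co.CodonCounts(counts))

    def test_cai_geometric_mean(self, code, make_sequence):
        counts = {c: 1 for c in code.degenerate_codons}
        counts["TTC"], counts["TTT"] = 8, 2
        w = co.cai_weights(co.CodonCounts(counts))
        # two included codons with w = 1 and w = 0.25 -> sqrt(0.25) = 0.5
        cds = make_sequence("g", ["TTC", "TTT"])
        assert co.cai(cds, w) == pytest.approx(0.5)

    def test_all_optimal_gene_cai_one(self, code, make_sequence):
        counts = {c: 1 for c in code.degenerate_codons}
        counts["GGC"] = 50
        w = co.cai_weights(co.CodonCounts(counts))
        assert co.cai(make_sequence("g", ["GGC", "GGC"]), w) == pytest.approx(1.0)

    def test_empty_inclusion_gives_nan(self, code, make_sequence):
        w = co.cai_weights(co.CodonCounts({c: 1 for c in code.degenerate_codons}))
        assert math.isnan(co.cai(make_sequence("g", ["ATG"]), w))


class TestFop:
    @pytest.mark.parametrize(
        "codons,expected",
        [
            (["GGC", "GGC", "TTC"], 1.0),
            (["GGA", "GGA"], 0.0),
            (["GGC", "GGC", "GGC", "GGA"], 0.75),
        ],
    )
    def test_fraction(self, make_sequence, expected, codons):
        optimal = {"GGC", "TTC"}
        assert co.fop(make_sequence("g", codons), optimal) == pytest.approx(expected)

    def test_met_trp_excluded_from_denominator(self, make_sequence):
        cds = make_sequence("g", ["ATG", "TGG", "GGC"])
        assert co.fop(cds, {"GGC"}) == pytest.approx(1.0)

    def test_no_degenerate_codons_gives_nan(self, make_sequence):
        assert math.isnan(co.fop(make_sequence("g", ["ATG"]), {"GGC"}))


def test_cai_fop_rank_correlated(small_world, small_classification):
    """CAI and Fop over one gene set are strongly positively rank-correlated."""
    ribo = co.concatenate_counts(small_world.cds["ribosomal"].values())
    w = co.cai_weights(ribo)
    optimal = small_classification.optimal_set
    genes = list(small_world.cds["testis"].values())[:80]
    cais = [co.cai(g, w) for g in genes]
    fops = [co.fop(g, optimal) for g in genes]
    rho = co.spearman(cais, fops)
    assert rho.statistic > 0.5


class TestFastaReading:
    def test_longest_cds_kept_per_gene(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(
            ">gene1 isoform A\nATGGGATAA\n"
            ">gene1 isoform B\nATGGGAGGAGGCTAA\n"
            ">gene2\nATGTTCTAA\n"
        )
        out = co.read_cds_fasta(fasta)
        assert set(out) == {"gene1", "gene2"}
        assert len(out["gene1"]) == 4  # longest isoform, stop stripped

    def test_wrapped_records_and_n_dropped(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">g1\nATGGGA\nGGC\n>g2\nATGNNNTAA\n")
        with pytest.warns(UserWarning):
            out = co.read_cds_fasta(fasta)
        assert set(out) == {"g1"}
        assert out["g1"].codons == ("ATG", "GGA", "GGC")

    def test_internal_stop_raises_unless_skipped(self, tmp_path):
        fasta = tmp_path / "in.fasta"
        fasta.write_text(">g1\nATGTAAGGA\n>g2\nATGGGCTAA\n")
        with pytest.raises(InternalStopError):
            co.read_cds_fasta(fasta)
        with pytest.warns(UserWarning):
            out = co.read_cds_fasta(fasta, skip_invalid=True)
        assert set(out) == {"g2"}
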