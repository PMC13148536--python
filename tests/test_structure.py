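"""Percent-Non-opt, RSA bins, secondary structure and the 18-aa sign test."""

import math

import numpy as np
import pandas as pd
import pytest

import codonopt as co
from codonopt.structure import assign_bin, normalize_ss_class


def residue_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "position", "aa", "rsa",
                                       "disorder", "ss_class"])


class TestJoin:
    def test_consistent_join(self, make_sequence):
        cds = make_sequence("g", ["GGA", "TTC", "ATG"])
        res = residue_frame([
            ("g", 1, "G", 0.5, 0.5, "coil"),
            ("g", 2, "F", 0.2, 0.1, "helix"),
            ("g", 3, "M", 0.4, 0.3, "coil"),
        ])
        joined = co.join_cds_structure(cds, res)
        assert list(joined["codon"]) == ["GGA", "TTC", "ATG"]

    def test_length_mismatch_errors(self, make_sequence):
        cds = make_sequence("g", ["GGA", "TTC", "ATG"])
        res = residue_frame([("g", i, "G", 0.5, 0.5, "coil") for i in range(1, 5)])
        with pytest.raises(ValueError, match="residues vs"):
            co.join_cds_structure(cds, res)

    def test_translation_mismatch_errors(self, make_sequence):
        cds = make_sequence("g", ["GGA"])
        res = residue_frame([("g", 1, "K", 0.5, 0.5, "coil")])
        with pytest.raises(ValueError, match="position 1"):
            co.join_cds_structure(cds, res)


class TestPercentNonOpt:
    def test_all_optimal_zero(self, make_sequence, truth_classification):
        opt = list(truth_classification.optimal.values())
        cds = make_sequence("g", opt[:5])
        assert co.percent_nonopt(cds, truth_classification) == pytest.approx(0.0)

    def test_constructed_73_percent_gene(self, make_sequence, truth_classification):
        # 73 of 100 degenerate codons non-optimal, plus Met/Trp that must not count
        nonopt = truth_classification.table.aa_to_codons["G"][0]  # GGA
        opt = truth_classification.optimal["G"]
        codons = ["GGA"] * 73 + [opt] * 27 + ["ATG", "TGG"]
        cds = make_sequence("mst-like", codons)
        pct = co.percent_nonopt(cds, truth_classification)
        assert pct == pytest.approx(73.0)
        assert assign_bin(pct) == "high"

    def test_boundary_bins(self):
        assert assign_bin(50.0) == "low"
        assert assign_bin(50.001) == "moderate"
        assert assign_bin(60.0) == "moderate"
        assert assign_bin(60.001) == "high"

    def test_percent_plus_complement_is_100(self, small_world, truth_classification):
        for cds in list(small_world.cds["testis"].values())[:20]:
            pct = co.percent_nonopt(cds, truth_classification)
            deg = set(truth_classification.table.degenerate_codons)
            included = [c for c in cds.codons if c in deg]
            pct_opt = 100.0 * sum(
                truth_classification.is_optimal(c) for c in included
            ) / len(included)
            assert pct + pct_opt == pytest.approx(100.0)

    def test_no_degenerate_codons_nan(self, make_sequence, truth_classification):
        assert math.isnan(
            co.percent_nonopt(make_sequence("g", ["ATG"]), truth_classification)
        )


class TestSSClasses:
    def test_eight_class_mapping(self):
        assert normalize_ss_class("H") == "helix"
        assert normalize_ss_class("G") == "helix"
        assert normalize_ss_class("E") == "strand"
        assert normalize_ss_class("B") == "strand"
        assert normalize_ss_class("T") == "coil"
        assert normalize_ss_class("coil") == "coil"
        with pytest.raises(ValueError):
            normalize_ss_class("X")

    def test_all_coil_composition(self):
        res = residue_frame([("g", i, "G", 0.5, 0.5, "coil") for i in range(1, 9)])
        comp, _ = co.ss_composition(res)
        assert comp.loc["coil", "fraction"] == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, small_world):
        comp, _ = co.ss_composition(small_world.structure)
        assert comp["fraction"].sum() == pytest.approx(1.0)

    def test_median_ordering_recovered(self, small_world):
        """Strand < helix < coil median RSA, as generated."""
        comp, pairs = co.ss_composition(small_world.structure)
        assert (
            comp.loc["strand", "median_rsa"]
            < comp.loc["helix", "median_rsa"]
            < comp.loc["coil", "median_rsa"]
        )
        assert (pairs["p"] < 0.05).all()


class TestBinComparison:
    def test_simulation_oracle_low_vs_high(self):
        """Beta-distributed gene RSA at means 0.40 vs 0.47 separates bins."""
        rng = np.random.default_rng(17)
        detected = 0
        for _ in range(10):
            low = rng.beta(0.40 * 30, 0.60 * 30, size=200)
            high = rng.beta(0.47 * 30, 0.53 * 30, size=200)
            summaries = pd.DataFrame(
                {
                    "bin": ["low"] * 200 + ["high"] * 200,
                    "mean_rsa": np.concatenate([low, high]),
                }
            )
            per_bin, pairs = co.bin_rsa_comparison(summaries)
            if (
                per_bin.loc["high", "median_rsa"] > per_bin.loc["low", "median_rsa"]
                and pairs["p"].iloc[0] < 0.05
            ):
                detected += 1
        assert detected >= 9  # >= 95% nominal detection at n = 200/bin

    def test_single_gene_bin_is_na(self):
        summaries = pd.DataFrame(
            {"bin": ["low", "low", "high"], "mean_rsa": [0.3, 0.4, 0.9]}
        )
        _, pairs = co.bin_rsa_comparison(summaries)
        assert math.isnan(pairs.loc[0, "p"])

    def test_identical_distributions_high_p(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=400)
        summaries = pd.DataFrame(
            {"bin": ["low"] * 200 + ["moderate"] * 200, "mean_rsa": vals}
        )
        _, pairs = co.bin_rsa_comparison(summaries)
        assert pairs.loc[0, "p"] > 0.05


class TestRSAByCodon:
    def build_residues(self, rng, cls, primary, mu=0.1, n=200):
        rows = []
        for aa in cls.table.degenerate_aas:
            for codon, shift in (
                (cls.optimal[aa], 0.0),
                (primary[aa], mu),
            ):
                rsa = np.clip(rng.beta(0.45 * 8, 0.55 * 8, size=n) + shift, 0, 1)
                for r in rsa:
                    rows.append({"gene_id": "g", "codon": codon, "aa": aa,
                                 "rsa": r, "disorder": r})
        return pd.DataFrame(rows)

    def test_direction_and_sign_test(self, truth_classification, small_world):
        rng = np.random.default_rng(23)
        primary_map = dict(small_world.truth.primary_nonopt)
        primary = pd.DataFrame(
            {"primary": pd.Series(primary_map)}
        ).rename_axis("aa")
        residues = self.build_residues(rng, truth_classification, primary_map)
        per_aa, sign = co.rsa_by_codon(residues, truth_classification, primary)
        assert int(sign.statistic) == 18 and sign.n == (18,)
        assert sign.p_value == pytest.approx(2 * 0.5**18)
        assert (per_aa["rsa_nonopt"] > per_aa["rsa_opt"]).all()

    def test_row_order_invariance(self, truth_classification, small_world):
        rng = np.random.default_rng(29)
        primary_map = dict(small_world.truth.primary_nonopt)
        primary = pd.DataFrame({"primary": pd.Series(primary_map)}).rename_axis("aa")
        residues = self.build_residues(rng, truth_classification, primary_map, n=50)
        a, _ = co.rsa_by_codon(residues, truth_classification, primary)
        shuffled = residues.sample(frac=1.0, random_state=1)
        b, _ = co.rsa_by_codon(shuffled, truth_classification, primary)
        pd.testing.assert_frame_equal(a, b)

    def test_few_comparable_aas_no_sign_test(self, truth_classification):
        primary = pd.DataFrame(
            {"primary": pd.Series({"G": "GGA"})}
        ).rename_axis("aa")
        residues = pd.DataFrame(
            [{"gene_id": "g", "codon": "GGA", "aa": "G", "rsa": 0.5, "disorder": 0.5},
             {"gene_id": "g", "codon": "GGC", "aa": "G", "rsa": 0.2, "disorder": 0.2}]
        )
        _, sign = co.rsa_by_codon(residues, truth_classification, primary)
        assert sign is None


class TestRSADisorder:
    def test_identity_correlation(self):
        vals = np.linspace(0, 1, 50)
        res = pd.DataFrame({"rsa": vals, "disorder": vals})
        assert co.rsa_disorder_correlation(res).statistic == pytest.approx(1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(31)
        res = pd.DataFrame(
            {"rsa": rng.uniform(size=2000), "disorder": rng.uniform(size=2000)}
        )
        assert abs(co.rsa_disorder_correlation(res).statistic) < 0.08

    def test_noisy_coupling_exceeds_reference_bound(self):
        """disorder = clip(rsa + noise, sd 0.2) at n = 10,000 gives rho >= 0.68."""
        rng = np.random.default_rng(37)
        rsa = rng.uniform(size=10_000)
        disorder = np.clip(rsa + rng.normal(0, 0.2, size=10_000), 0, 1)
        res = pd.DataFrame({"rsa": rsa, "disorder": disorder})
        assert co.rsa_disorder_correlation(res).statistic >= 0.68


def test_gene_structure_summary_and_tsv(small_world, truth_classification, tmp_path):
    cds_map = small_world.cds["testis"]
    summaries = co.gene_structure_summary(
        cds_map, small_world.structure, truth_classification
    )
    assert set(summaries.index) == set(cds_map)
    non_na = summaries["percent_nonopt"].dropna()
    bins = summaries.loc[non_na.index, "bin"]
    assert bins.isin(["low", "moderate", "high"]).all()  # partition
    # structure TSV round trip preserves the residue table
    path = tmp_path / "structure.tsv"
    small_world.structure.to_csv(path, sep="\t", index=False)
    loaded = co.structure.read_structure_table(path)
    pd.testing.assert_frame_equal(
        loaded, small_world.structure, check_dtype=False
    )
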