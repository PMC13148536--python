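"""Linking codon usage to per-residue protein structure.

Consumes per-residue tables of relative solvent accessibility (RSA),
disorder probability, and secondary-structure class (as produced by
NetsurfP-style predictors) aligned to CDS codons, and computes:

* Percent-Non-opt per gene (share of degenerate-amino-acid codons that are
  non-optimal) with low / moderate / high bins at 50% and 60%;
* per-bin gene-wide RSA comparisons (Mann-Whitney U);
* secondary-structure composition and per-class RSA;
* per-amino-acid mean RSA when encoded by the primary non-optimal codon
  versus the optimal codon, with an exact sign test over amino acids;
* the RSA-disorder rank correlation.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .classification import CodonClassification
from .genetic_code import CodingSequence, CodonTable, STANDARD_CODE
from .stats import TestResult, mwu, sign_test, spearman

__all__ = [
    "SS_CLASSES",
    "normalize_ss_class",
    "read_structure_table",
    "join_cds_structure",
    "percent_nonopt",
    "assign_bin",
    "gene_structure_summary",
    "bin_rsa_comparison",
    "ss_composition",
    "rsa_by_codon",
    "rsa_disorder_correlation",
]

SS_CLASSES = ("helix", "strand", "coil")

# DSSP-style 8-class to 3-class mapping: H/G/I -> helix, E/B -> strand,
# everything else -> coil.
_SS8_TO_3 = {
    "H": "helix",
    "G": "helix",
    "I": "helix",
    "E": "strand",
    "B": "strand",
    "T": "coil",
    "S": "coil",
    "C": "coil",
    "-": "coil",
}


def normalize_ss_class(label: str) -> str:
    s = str(label).strip()
    if s.lower() in SS_CLASSES:
        return s.lower()
    if s.upper() in _SS8_TO_3:
        return _SS8_TO_3[s.upper()]
    raise ValueError(f"unknown secondary-structure label {label!r}")


def read_structure_table(path) -> pd.DataFrame:
    """Read a per-residue TSV (gene_id, position, aa, rsa, disorder, ss_class)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "position", "aa", "rsa", "disorder", "ss_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"structure table missing columns: {sorted(missing)}")
    df = df.copy()
    df["ss_class"] = df["ss_class"].map(normalize_ss_class)
    for col in ("rsa", "disorder"):
        vals = df[col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return df


def join_cds_structure(
    cds: CodingSequence,
    residues: pd.DataFrame,
    table: CodonTable = STANDARD_CODE,
) -> pd.DataFrame:
    """Pair each residue row with the codon at the same position.

    The residue table must cover exactly the protein (positions 1..L in any
    order) and each codon must translate to the recorded amino acid.
    """
    sub = residues.sort_values("position")
    if len(sub) != len(cds):
        raise ValueError(
            f"{cds.gene_id}: {len(sub)} residues vs {len(cds)} codons"
        )
    codons = [cds.codons[int(p) - 1] for p in sub["position"]]
    for pos, codon, aa in zip(sub["position"], codons, sub["aa"]):
        if table.codon_to_aa[codon] != aa:
            raise ValueError(
                f"{cds.gene_id}: position {int(pos)} codon {codon} "
                f"translates to {table.codon_to_aa[codon]}, table says {aa}"
            )
    out = sub.copy()
    out["codon"] = codons
    return out


def percent_nonopt(
    cds: CodingSequence, cls: CodonClassification
) -> float:
    """Percent of a gene's degenerate-aa codons that are non-optimal (0-100).

    Met, Trp and stop codons are excluded from the denominator. NaN when the
    gene has no degenerate-amino-acid codons.
    """
    deg = set(cls.table.degenerate_codons)
    included = [c for c in cds.codons if c in deg]
    if not included:
        return math.nan
    n_nonopt = sum(not cls.is_optimal(c) for c in included)
    return 100.0 * n_nonopt / len(included)


def assign_bin(percent: float, low: float = 50.0, high: float = 60.0) -> str | None:
    """Bin Percent-Non-opt into low (<=50), moderate (50-60], high (>60)."""
    if percent is None or math.isnan(percent):
        return None
    if percent <= low:
        return "low"
    if percent <= high:
        return "moderate"
    return "high"


def gene_structure_summary(
    cds_map: Mapping[str, CodingSequence],
    residues: pd.DataFrame,
    cls: CodonClassification,
    rsa_stat: str = "mean",
) -> pd.DataFrame:
    """Per-gene Percent-Non-opt, bin, and gene-wide RSA.

    ``rsa_stat`` selects mean (default) or median RSA over the gene's
    residues. Genes absent from the residue table get NaN RSA.
    """
    agg = getattr(residues.groupby("gene_id")["rsa"], rsa_stat)()
    counts = residues.groupby("gene_id").size()
    rows = []
    for gene_id, cds in cds_map.items():
        pct = percent_nonopt(cds, cls)
        rows.append(
            {
                "gene_id": gene_id,
                "percent_nonopt": pct,
                "bin": assign_bin(pct),
                "mean_rsa": float(agg.get(gene_id, math.nan)),
                "n_residues": int(counts.get(gene_id, 0)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def bin_rsa_comparison(
    summaries: pd.DataFrame, min_genes: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin RSA medians/means plus pairwise Mann-Whitney U tests."""
    order = ["low", "moderate", "high"]
    present = [b for b in order if (summaries["bin"] == b).any()]
    stats_rows = []
    groups: dict[str, np.ndarray] = {}
    for b in present:
        vals = summaries.loc[summaries["bin"] == b, "mean_rsa"].dropna().to_numpy()
        groups[b] = vals
        stats_rows.append(
            {
                "bin": b,
                "n_genes": int(vals.size),
                "median_rsa": float(np.median(vals)) if vals.size else math.nan,
                "mean_rsa": float(vals.mean()) if vals.size else math.nan,
            }
        )
    per_bin = pd.DataFrame(stats_rows).set_index("bin")
    pair_rows = []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            a, b = groups[present[i]], groups[present[j]]
            if a.size >= min_genes and b.size >= min_genes:
                res = mwu(a, b)
                u, p = res.statistic, res.p_value
            else:
                u, p = math.nan, math.nan
            pair_rows.append(
                {
                    "bin_a": present[i],
                    "bin_b": present[j],
                    "U": u,
                    "p": p,
                }
            )
    return per_bin, pd.DataFrame(pair_rows)


def ss_composition(residues: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Residue fractions and median RSA per secondary-structure class."""
    if residues.empty:
        raise ValueError("empty residue set")
    total = len(residues)
    rows = []
    groups = {}
    for ss in SS_CLASSES:
        sub = residues.loc[residues["ss_class"] == ss, "rsa"].to_numpy()
        groups[ss] = sub
        rows.append(
            {
                "ss_class": ss,
                "fraction": sub.size / total,
                "median_rsa": float(np.median(sub)) if sub.size else math.nan,
                "n_residues": int(sub.size),
            }
        )
    comp = pd.DataFrame(rows).set_index("ss_class")
    pair_rows = []
    for i in range(len(SS_CLASSES)):
        for j in range(i + 1, len(SS_CLASSES)):
            a, b = groups[SS_CLASSES[i]], groups[SS_CLASSES[j]]
            if a.size >= 1 and b.size >= 1:
                res = mwu(a, b)
                u, p = res.statistic, res.p_value
            else:
                u, p = math.nan, math.nan
            pair_rows.append(
                {"class_a": SS_CLASSES[i], "class_b": SS_CLASSES[j], "U": u, "p": p}
            )
    return comp, pd.DataFrame(pair_rows)


def rsa_by_codon(
    residues: pd.DataFrame,
    cls: CodonClassification,
    primary: pd.DataFrame,
    min_aas: int = 5,
    stat: str = "mean",
) -> tuple[pd.DataFrame, TestResult | None]:
    """Mean RSA per amino acid under its primary non-optimal vs optimal codon.

    ``residues`` must carry a ``codon`` column (see
    :func:`join_cds_structure`). Amino acids lacking residues under either
    codon, or lacking a primary call, are excluded from the sign test
    (reported with NaN means). The sign test is the exact two-sided
    binomial on the number of amino acids whose non-optimal mean exceeds
    the optimal mean; it is None when fewer than ``min_aas`` amino acids
    are comparable.
    """
    table = cls.table
    rows = []
    n_higher = 0
    n_compared = 0
    by_codon = residues.groupby("codon")["rsa"]
    agg = by_codon.mean() if stat == "mean" else by_codon.median()
    sem = by_codon.sem()
    counts = by_codon.size()
    for aa in table.degenerate_aas:
        opt_codon = cls.optimal[aa]
        prim_codon = primary.loc[aa, "primary"] if aa in primary.index else None
        row = {
            "aa": aa,
            "optimal_codon": opt_codon,
            "primary_nonopt_codon": prim_codon,
            "rsa_opt": float(agg.get(opt_codon, math.nan)),
            "se_opt": float(sem.get(opt_codon, math.nan)),
            "n_opt": int(counts.get(opt_codon, 0)),
            "rsa_nonopt": math.nan,
            "se_nonopt": math.nan,
            "n_nonopt": 0,
        }
        if prim_codon is not None and not (
            isinstance(prim_codon, float) and math.isnan(prim_codon)
        ):
            row["rsa_nonopt"] = float(agg.get(prim_codon, math.nan))
            row["se_nonopt"] = float(sem.get(prim_codon, math.nan))
            row["n_nonopt"] = int(counts.get(prim_codon, 0))
        comparable = row["n_opt"] >= 1 and row["n_nonopt"] >= 1
        row["compared"] = comparable
        if comparable:
            n_compared += 1
            if row["rsa_nonopt"] > row["rsa_opt"]:
                n_higher += 1
        rows.append(row)
    per_aa = pd.DataFrame(rows).set_index("aa")
    test = sign_test(n_higher, n_compared) if n_compared >= min_aas else None
    return per_aa, test


def rsa_disorder_correlation(residues: pd.DataFrame) -> TestResult:
    """Spearman correlation between per-residue RSA and disorder score."""
    if len(residues) < 10:
        raise ValueError("need >= 10 residues")
    return spearman(
        residues["rsa"].to_numpy(), residues["disorder"].to_numpy()
    )
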