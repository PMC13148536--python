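"""Per-gene RSCU matrices, gene-set delta-RSCU contrasts, primary non-optimal
codon calls, and extreme-use fractions.

A contrast between two gene sets computes, per degenerate-amino-acid codon,
the difference of mean per-gene RSCU (genes lacking the amino acid drop out
pairwise) together with a two-sample t-test. The "primary" non-optimal codon
of an amino acid is the non-optimal codon with the largest positive mean
delta-RSCU in the testis-versus-unbiased contrast, gated on a positive
delta in the testis-versus-ovary contrast as well.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classification import CodonClassification
from .genetic_code import CodingSequence, CodonTable, STANDARD_CODE, count_codons, rscu
from .stats import chi_square

__all__ = [
    "rscu_matrix",
    "contrast",
    "identify_primary_nonoptimal",
    "extreme_use",
    "extreme_use_table",
]


def rscu_matrix(
    genes: Iterable[CodingSequence] | Mapping[str, CodingSequence],
    table: CodonTable = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-gene RSCU over the 59 degenerate-aa codons (NaN where absent)."""
    if isinstance(genes, Mapping):
        genes = list(genes.values())
    else:
        genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    codons = list(table.degenerate_codons)
    rows = np.empty((len(genes), len(codons)))
    ids = []
    for i, g in enumerate(genes):
        profile = rscu(count_codons(g), table)
        rows[i] = [profile.values[c] for c in codons]
        ids.append(g.gene_id)
    return pd.DataFrame(rows, index=ids, columns=codons)


def contrast(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    equal_var: bool = False,
    adjust: str = "none",
    table: CodonTable = STANDARD_CODE,
) -> pd.DataFrame:
    """Per-codon mean delta-RSCU (A minus B) with two-sample t-tests.

    Welch's t by default (``equal_var=True`` gives Student's). Genes
    contribute only where the amino acid occurs (pairwise deletion). Codons
    with fewer than two contributing genes in either set keep their delta
    but get NaN test results. ``adjust="bh"`` adds Benjamini-Hochberg
    adjusted p-values.
    """
    codons = list(table.degenerate_codons)
    if list(set_a.columns) != codons or list(set_b.columns) != codons:
        set_a = set_a.reindex(columns=codons)
        set_b = set_b.reindex(columns=codons)
    rows = []
    for codon in codons:
        a = set_a[codon].dropna().to_numpy()
        b = set_b[codon].dropna().to_numpy()
        delta = (a.mean() if a.size else math.nan) - (
            b.mean() if b.size else math.nan
        )
        if a.size >= 2 and b.size >= 2:
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                # degenerate: zero variance in both groups
                t_stat, p = (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
            else:
                t_stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        else:
            t_stat, p = math.nan, math.nan
        rows.append(
            {
                "codon": codon,
                "aa": table.codon_to_aa[codon],
                "delta": float(delta),
                "t": float(t_stat),
                "p": float(p),
                "n_A": int(a.size),
                "n_B": int(b.size),
            }
        )
    out = pd.DataFrame(rows).set_index("codon")
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna()
        adj = pd.Series(np.nan, index=out.index)
        if ok.any():
            adj[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_adj"] = adj
    return out


def identify_primary_nonoptimal(
    contrast_to: pd.DataFrame,
    contrast_tu: pd.DataFrame,
    cls: CodonClassification,
    secondary_frac: float = 0.8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call the primary (preferred) non-optimal codon per degenerate amino acid.

    Among an amino acid's non-optimal codons the candidate is the argmax of
    the testis-versus-unbiased mean delta-RSCU (the better-powered
    contrast); it is called primary only when both that delta and the
    testis-versus-ovary delta are positive, otherwise the amino acid gets
    no call. The runner-up is reported as secondary when its
    testis-versus-unbiased delta reaches ``secondary_frac`` of the
    primary's. Returns one row per amino acid.
    """
    table = cls.table
    rows = []
    for aa in table.degenerate_aas:
        nonopt = [
            c for c in table.aa_to_codons[aa] if not cls.is_optimal(c)
        ]
        ranked = sorted(
            nonopt, key=lambda c: contrast_tu.loc[c, "delta"], reverse=True
        )
        best = ranked[0]
        d_tu = float(contrast_tu.loc[best, "delta"])
        d_to = float(contrast_to.loc[best, "delta"])
        called = d_tu > 0 and d_to > 0
        secondary = None
        if called and len(ranked) > 1:
            runner = ranked[1]
            d_runner = float(contrast_tu.loc[runner, "delta"])
            if d_runner > 0 and d_runner >= secondary_frac * d_tu:
                secondary = runner
        rows.append(
            {
                "aa": aa,
                "primary": best if called else None,
                "delta_TO": d_to,
                "delta_TU": d_tu,
                "p_TO": float(contrast_to.loc[best, "p"]),
                "p_TU": float(contrast_tu.loc[best, "p"]),
                "significant_TO": bool(contrast_to.loc[best, "p"] < alpha),
                "significant_TU": bool(contrast_tu.loc[best, "p"] < alpha),
                "secondary": secondary,
            }
        )
    return pd.DataFrame(rows).set_index("aa")


def extreme_use(
    matrix: pd.DataFrame, codon: str, threshold: float = 1.5
) -> float:
    """Fraction of genes using a codon at RSCU >= threshold (NaN rows excluded)."""
    col = matrix[codon].dropna()
    if col.empty:
        return math.nan
    return float((col >= threshold).mean())


def extreme_use_table(
    matrices: Mapping[str, pd.DataFrame], codon: str, threshold: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extreme-use fractions per gene set plus pairwise 2x2 chi-square tests."""
    rows = []
    counts: dict[str, tuple[int, int]] = {}
    for label, m in matrices.items():
        col = m[codon].dropna()
        k = int((col >= threshold).sum())
        n = int(col.size)
        counts[label] = (k, n)
        rows.append(
            {
                "gene_set": label,
                "fraction": (k / n) if n else math.nan,
                "n_extreme": k,
                "n_genes": n,
            }
        )
    fractions = pd.DataFrame(rows).set_index("gene_set")
    labels = list(matrices)
    pair_rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ka, na = counts[labels[i]]
            kb, nb = counts[labels[j]]
            table_2x2 = [[ka, na - ka], [kb, nb - kb]]
            try:
                res = chi_square(table_2x2)
                stat, p = res.statistic, res.p_value
            except ValueError:
                stat, p = math.nan, math.nan
            pair_rows.append(
                {
                    "set_a": labels[i],
                    "set_b": labels[j],
                    "chi2": stat,
                    "p": p,
                }
            )
    return fractions, pd.DataFrame(pair_rows)
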