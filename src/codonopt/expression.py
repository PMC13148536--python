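"""Sex-bias classification, tissue-specificity (tau), and gene subclasses.

Genes are classified from a gene x tissue RPKM matrix against a focal gonad
pair (testis, ovary): sex-biased when expression in one gonad is at least
``min_rpkm`` and at least ``fold``-times the other gonad, unbiased when the
fold-bias is below ``fold`` but at least one gonad reaches ``min_rpkm``,
otherwise excluded. Tissue specificity uses the tau index,

    tau = sum_i (1 - x_i / max(x)) / (n_tissues - 1),

which is 0 for uniform expression and 1 for single-tissue expression.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import CodingSequence

__all__ = [
    "ExpressionMatrix",
    "tau",
    "tau_profile",
    "classify_sex_bias",
    "subclass",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x tissues RPKM values with a designated focal gonad pair."""

    values: pd.DataFrame  # index: gene ids; columns: tissue labels
    focal: tuple[str, str] = ("testis", "ovary")

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative RPKM values")
        for t in self.focal:
            if t not in self.values.columns:
                raise ValueError(f"focal tissue {t!r} absent from matrix")


def tau(expression_row) -> float:
    """Tissue-specificity index of one gene's expression vector."""
    x = np.asarray(expression_row, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires >= 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression values")
    top = x.max()
    if top == 0:
        return math.nan
    return float((1.0 - x / top).sum() / (x.size - 1))


def tau_profile(
    expr: ExpressionMatrix, log_transform: bool = False
) -> pd.Series:
    """tau per gene over the full tissue panel.

    With ``log_transform`` the row is log2(x+1)-transformed first (an
    option; the default works on untransformed RPKM).
    """
    values = expr.values
    x = values.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    top = x.max(axis=1)
    out = np.full(x.shape[0], np.nan)
    nz = top > 0
    out[nz] = (1.0 - x[nz] / top[nz, None]).sum(axis=1) / (x.shape[1] - 1)
    return pd.Series(out, index=values.index, name="tau")


def classify_sex_bias(
    expr: ExpressionMatrix,
    min_rpkm: float = 100.0,
    fold: float = 5.0,
    pseudocount: float = 0.01,
    sex_specific_floor: float = 1.0,
    log_transform_tau: bool = False,
) -> pd.DataFrame:
    """Classify each gene as testis-biased / ovary-biased / unbiased / excluded.

    Fold-bias is computed after adding ``pseudocount`` RPKM to both focal
    values so zero denominators stay finite. ``sex_specific`` is True for
    sex-biased genes whose minor gonad falls below ``sex_specific_floor``.
    Returns a DataFrame indexed by gene id with columns sex_class,
    fold_bias, tau and sex_specific.
    """
    t_label, o_label = expr.focal
    t = expr.values[t_label].to_numpy(dtype=float)
    o = expr.values[o_label].to_numpy(dtype=float)
    missing = np.isnan(t) | np.isnan(o)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} genes lack focal tissue values; excluded"
        )
    # pseudocount applied only where a focal value is zero, so exact printed
    # thresholds (e.g. a gene at precisely 5-fold bias) stay on their boundary
    zero = (t == 0) | (o == 0)
    ratio = np.where(
        zero, (t + pseudocount) / (o + pseudocount), t / np.where(o == 0, 1.0, o)
    )
    fold_bias = np.where(ratio >= 1.0, ratio, 1.0 / ratio)

    sex_class = np.full(len(t), "excluded", dtype=object)
    testis_biased = (ratio >= fold) & (t >= min_rpkm)
    ovary_biased = (1.0 / ratio >= fold) & (o >= min_rpkm)
    unbiased = (fold_bias < fold) & (np.maximum(t, o) >= min_rpkm)
    sex_class[testis_biased] = "testis_biased"
    sex_class[ovary_biased] = "ovary_biased"
    sex_class[unbiased] = "unbiased"
    sex_class[missing] = "excluded"

    minor = np.minimum(t, o)
    sex_specific = (testis_biased | ovary_biased) & (minor < sex_specific_floor)

    return pd.DataFrame(
        {
            "sex_class": sex_class,
            "fold_bias": fold_bias,
            "tau": tau_profile(expr, log_transform=log_transform_tau),
            "sex_specific": sex_specific,
        },
        index=expr.values.index,
    )


def subclass(
    records: pd.DataFrame,
    expr: ExpressionMatrix,
    cds: dict[str, CodingSequence],
    length_cutoff: int = 272,
    extreme_rpkm: float = 200.0,
) -> pd.DataFrame:
    """Add expression and CDS-length subclasses to sex-bias records.

    ``expr_class`` splits the focal expression level (the larger of the two
    gonads) at ``extreme_rpkm``: "extreme" for >= 200 RPKM, "high" for the
    100-200 band, NA below. ``length_class`` is "long" for >= 272 codons
    (33rd-percentile cutoff), "short" below; NA for genes without a CDS.
    """
    t_label, o_label = expr.focal
    peak = expr.values[[t_label, o_label]].max(axis=1).reindex(records.index)
    expr_class = pd.Series(pd.NA, index=records.index, dtype=object)
    expr_class[peak >= extreme_rpkm] = "extreme"
    expr_class[(peak >= 100.0) & (peak < extreme_rpkm)] = "high"

    n_codons = pd.Series(
        {g: len(cds[g]) for g in records.index if g in cds}, dtype=float
    ).reindex(records.index)
    length_class = pd.Series(pd.NA, index=records.index, dtype=object)
    length_class[n_codons >= length_cutoff] = "long"
    length_class[n_codons < length_cutoff] = "short"

    out = records.copy()
    out["expr_class"] = expr_class
    out["length_class"] = length_class
    out["n_codons"] = n_codons
    return out
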