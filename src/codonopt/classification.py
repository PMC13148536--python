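"""A-priori organism-wide optimal/non-optimal codon calling.

The optimal codon of each degenerate amino acid is the one with the largest
positive difference in RSCU between a highly expressed reference set
(ribosomal protein genes) and the genome background (all genes), computed on
concatenated counts. All 41 remaining degenerate-amino-acid codons are
non-optimal. Each codon is further stratified by its exact-match tRNA gene
copy number into the four categories Opt_high-tRNAs, Opt_wobble,
Non-opt_low-tRNAs and Non-opt_high-tRNAs; high versus low is demarcated by
the median copy number over the 59 degenerate-amino-acid codons, and wobble
is reserved for optimal codons with zero exact matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genetic_code import (
    CodonCounts,
    CodonTable,
    RSCUProfile,
    STANDARD_CODE,
    rscu,
)

__all__ = [
    "TRNATable",
    "CodonClassification",
    "delta_rscu_reference",
    "assign_optimal",
    "trna_status",
    "classify_codons",
    "read_trna_table",
    "write_classification",
    "read_classification",
]

OPT_HIGH = "Opt_high-tRNAs"
OPT_WOBBLE = "Opt_wobble"
NONOPT_LOW = "Non-opt_low-tRNAs"
NONOPT_HIGH = "Non-opt_high-tRNAs"


@dataclass(frozen=True)
class TRNATable:
    """Exact-match tRNA gene copy number per codon; missing codons count 0."""

    counts: Mapping[str, int]
    species: str = ""

    def get(self, codon: str) -> int:
        return int(self.counts.get(codon, 0))


@dataclass(frozen=True)
class CodonClassification:
    """Per-codon optimality calls over the 59 degenerate-aa codons.

    ``optimal`` maps each degenerate amino acid to its single optimal codon;
    ``optimality`` is "optimal"/"non_optimal" per codon; ``trna_status`` and
    ``combined`` are filled by :func:`trna_status`. ``flags`` records ties
    and amino acids whose best delta-RSCU was not positive.
    """

    delta_rscu: Mapping[str, float]
    optimal: Mapping[str, str]
    optimality: Mapping[str, str]
    flags: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    trna_status: Mapping[str, str] = field(default_factory=dict)
    combined: Mapping[str, str] = field(default_factory=dict)
    trna_threshold: float = math.nan
    table: CodonTable = STANDARD_CODE

    @property
    def optimal_set(self) -> frozenset[str]:
        return frozenset(self.optimal.values())

    def is_optimal(self, codon: str) -> bool:
        return self.optimality.get(codon) == "optimal"


def delta_rscu_reference(
    ribosomal_rscu: RSCUProfile,
    background_rscu: RSCUProfile,
    table: CodonTable = STANDARD_CODE,
) -> dict[str, float]:
    """Elementwise RSCU difference (reference minus background).

    Both profiles must come from concatenated counts with every degenerate
    amino acid observed; per amino acid the differences sum to zero since
    each profile sums to the degeneracy.
    """
    delta: dict[str, float] = {}
    for codon in table.degenerate_codons:
        a = ribosomal_rscu.values.get(codon, math.nan)
        b = background_rscu.values.get(codon, math.nan)
        if math.isnan(a) or math.isnan(b):
            raise ValueError(
                f"RSCU undefined for degenerate codon {codon}; "
                "profiles must cover all 18 degenerate amino acids"
            )
        delta[codon] = a - b
    return delta


def assign_optimal(
    delta: Mapping[str, float], table: CodonTable = STANDARD_CODE
) -> CodonClassification:
    """Call one optimal codon per degenerate amino acid by argmax delta-RSCU.

    Ties break to the lexicographically first codon and are flagged; an
    amino acid whose maximum delta is not positive is still assigned its
    argmax but flagged ``no_positive_optimal``.
    """
    missing = [c for c in table.degenerate_codons if c not in delta]
    if missing:
        raise ValueError(f"delta-RSCU missing codons: {missing[:5]}")
    optimal: dict[str, str] = {}
    optimality: dict[str, str] = {}
    flags: dict[str, tuple[str, ...]] = {}
    for aa in table.degenerate_aas:
        codons = table.aa_to_codons[aa]  # sorted lexicographically
        top = max(delta[c] for c in codons)
        winners = [c for c in codons if delta[c] == top]
        best = winners[0]
        aa_flags = []
        if len(winners) > 1:
            aa_flags.append("tie")
        if top <= 0:
            aa_flags.append("no_positive_optimal")
        optimal[aa] = best
        for c in codons:
            optimality[c] = "optimal" if c == best else "non_optimal"
        if aa_flags:
            flags[aa] = tuple(aa_flags)
    return CodonClassification(
        delta_rscu=dict(delta),
        optimal=optimal,
        optimality=optimality,
        flags=flags,
        table=table,
    )


def trna_status(
    trna: TRNATable, classification: CodonClassification
) -> CodonClassification:
    """Stratify the classified codons by exact-match tRNA gene abundance.

    The high/low threshold is the median copy number over the 59
    degenerate-amino-acid codons; strictly greater than the median is high.
    An optimal codon with zero exact matches is a wobble codon; non-optimal
    codons with zero matches fold into the low class.
    """
    table = classification.table
    counts = np.array([trna.get(c) for c in table.degenerate_codons], dtype=float)
    threshold = float(np.median(counts))
    status: dict[str, str] = {}
    combined: dict[str, str] = {}
    for codon in table.degenerate_codons:
        n = trna.get(codon)
        opt = classification.is_optimal(codon)
        if opt and n == 0:
            status[codon] = "wobble"
            combined[codon] = OPT_WOBBLE
        elif n > threshold:
            status[codon] = "high_trna"
            combined[codon] = OPT_HIGH if opt else NONOPT_HIGH
        else:
            status[codon] = "low_trna"
            # The four-category scheme has no Opt_low class; an optimal codon
            # with few-but-nonzero exact matches (absent from the reference
            # organism's data) gets an explicit out-of-scheme label.
            combined[codon] = "Opt_low-tRNAs" if opt else NONOPT_LOW
    return replace(
        classification,
        trna_status=status,
        combined=combined,
        trna_threshold=threshold,
    )


def classify_codons(
    ribosomal_counts: CodonCounts,
    background_counts: CodonCounts,
    trna: TRNATable | None = None,
    table: CodonTable = STANDARD_CODE,
) -> CodonClassification:
    """Full a-priori classification from concatenated reference/background counts."""
    delta = delta_rscu_reference(
        rscu(ribosomal_counts, table), rscu(background_counts, table), table
    )
    cls = assign_optimal(delta, table)
    if trna is not None:
        cls = trna_status(trna, cls)
    return cls


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------


def read_trna_table(path: str | Path, species: str = "") -> TRNATable:
    """Read a 2-column TSV (codon, count)."""
    df = pd.read_csv(path, sep="\t")
    codon_col, count_col = df.columns[:2]
    counts = {
        str(c).upper(): int(n) for c, n in zip(df[codon_col], df[count_col])
    }
    return TRNATable(counts=counts, species=species)


def write_trna_table(trna: TRNATable, path: str | Path) -> None:
    rows = sorted(trna.counts.items())
    pd.DataFrame(rows, columns=["codon", "count"]).to_csv(
        path, sep="\t", index=False
    )


def classification_frame(cls: CodonClassification) -> pd.DataFrame:
    table = cls.table
    rows = []
    for codon in table.degenerate_codons:
        rows.append(
            {
                "codon": codon,
                "aa": table.codon_to_aa[codon],
                "delta_rscu": cls.delta_rscu[codon],
                "optimality": cls.optimality[codon],
                "trna_status": cls.trna_status.get(codon, ""),
                "combined_label": cls.combined.get(codon, ""),
            }
        )
    return pd.DataFrame(rows)


def write_classification(cls: CodonClassification, path: str | Path) -> None:
    classification_frame(cls).to_csv(path, sep="\t", index=False)


def read_classification(
    path: str | Path, table: CodonTable = STANDARD_CODE
) -> CodonClassification:
    df = pd.read_csv(path, sep="\t").fillna("")
    delta = dict(zip(df["codon"], df["delta_rscu"].astype(float)))
    optimality = dict(zip(df["codon"], df["optimality"]))
    optimal = {
        table.codon_to_aa[c]: c
        for c, o in optimality.items()
        if o == "optimal"
    }
    return CodonClassification(
        delta_rscu=delta,
        optimal=optimal,
        optimality=optimality,
        trna_status=dict(zip(df["codon"], df["trna_status"])),
        combined=dict(zip(df["codon"], df["combined_label"])),
        table=table,
    )
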