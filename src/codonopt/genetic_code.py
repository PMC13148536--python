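"""Genetic-code model, codon counting, and core codon-usage statistics.

The standard genetic code has 61 sense codons. Methionine and tryptophan are
encoded by a single codon each, leaving 18 amino acids with two or more
synonymous codons ("degenerate amino acids") and 59 codons belonging to them.
All optimality statistics in this package (RSCU-based classification, CAI,
Fop, Percent-Non-opt) are defined over those 59 codons only.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

__all__ = [
    "CodonTable",
    "STANDARD_CODE",
    "CodingSequence",
    "CodonCounts",
    "RSCUProfile",
    "CAIWeights",
    "InvalidSequenceError",
    "InternalStopError",
    "AmbiguousNucleotideError",
    "ReferenceCoverageError",
    "count_codons",
    "concatenate_counts",
    "rscu",
    "cai_weights",
    "cai",
    "fop",
    "read_cds_fasta",
]


class InvalidSequenceError(ValueError):
    """A coding sequence violates a structural requirement."""


class InternalStopError(InvalidSequenceError):
    """A stop codon occurs before the final codon."""


class AmbiguousNucleotideError(InvalidSequenceError):
    """The sequence contains characters outside {A, C, G, T}."""


class ReferenceCoverageError(ValueError):
    """A CAI reference set lacks every codon of some degenerate amino acid."""


# ---------------------------------------------------------------------------
# Code table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code with its degeneracy structure.

    Attributes
    ----------
    codon_to_aa:
        Map from each of the 61 sense codons (uppercase DNA) to its
        one-letter amino-acid symbol.
    stop_codons:
        The three stop codons.
    aa_to_codons:
        Inverse grouping; codons sorted lexicographically per amino acid.
    degeneracy:
        Number of synonymous codons per amino acid.
    degenerate_aas:
        The 18 amino acids with degeneracy >= 2, sorted.
    degenerate_codons:
        The 59 sense codons of degenerate amino acids, sorted.
    """

    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    aa_to_codons: Mapping[str, tuple[str, ...]] = field(init=False)
    degeneracy: Mapping[str, int] = field(init=False)
    degenerate_aas: tuple[str, ...] = field(init=False)
    degenerate_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        groups: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            groups.setdefault(aa, []).append(codon)
        aa_to_codons = {aa: tuple(sorted(cs)) for aa, cs in groups.items()}
        degeneracy = {aa: len(cs) for aa, cs in aa_to_codons.items()}
        deg_aas = tuple(sorted(aa for aa, d in degeneracy.items() if d >= 2))
        deg_codons = tuple(
            sorted(c for c, aa in self.codon_to_aa.items() if degeneracy[aa] >= 2)
        )
        object.__setattr__(self, "aa_to_codons", aa_to_codons)
        object.__setattr__(self, "degeneracy", degeneracy)
        object.__setattr__(self, "degenerate_aas", deg_aas)
        object.__setattr__(self, "degenerate_codons", deg_codons)

    @classmethod
    def standard(cls) -> "CodonTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[1]
        return cls(
            codon_to_aa=dict(bio.forward_table),
            stop_codons=frozenset(bio.stop_codons),
        )

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[codon]


STANDARD_CODE = CodonTable.standard()


# ---------------------------------------------------------------------------
# Coding sequences and codon counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingSequence:
    """One gene's CDS as an ordered tuple of sense codons.

    The terminal stop codon, if present in the source nucleotide sequence,
    is stripped at construction. Internal stops and ambiguous nucleotides
    are rejected.
    """

    gene_id: str
    codons: tuple[str, ...]

    @classmethod
    def from_sequence(
        cls, gene_id: str, sequence: str, table: CodonTable = STANDARD_CODE
    ) -> "CodingSequence":
        seq = str(sequence).upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise InvalidSequenceError(
                f"{gene_id}: length {len(seq)} not divisible by 3"
            )
        if set(seq) - {"A", "C", "G", "T"}:
            bad = sorted(set(seq) - {"A", "C", "G", "T"})
            raise AmbiguousNucleotideError(
                f"{gene_id}: ambiguous nucleotides {bad}"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in table.stop_codons:
            codons = codons[:-1]
        for i, c in enumerate(codons):
            if c in table.stop_codons:
                raise InternalStopError(
                    f"{gene_id}: internal stop codon {c} at codon {i + 1}"
                )
        return cls(gene_id=gene_id, codons=tuple(codons))

    def __len__(self) -> int:
        return len(self.codons)

    def protein(self, table: CodonTable = STANDARD_CODE) -> str:
        return "".join(table.codon_to_aa[c] for c in self.codons)


@dataclass(frozen=True)
class CodonCounts:
    """Raw codon tallies for one gene or a concatenated gene set."""

    counts: Mapping[str, int]
    source: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def count_codons(cds: CodingSequence) -> CodonCounts:
    """Tally sense codons of a CDS (terminal stop already stripped)."""
    return CodonCounts(counts=dict(Counter(cds.codons)), source=cds.gene_id)


def concatenate_counts(
    genes: Iterable[CodingSequence], source: str = "concatenated"
) -> CodonCounts:
    """Codon counts of the concatenation of several genes.

    Equals the element-wise sum of per-gene counts (additivity).
    """
    acc: Counter[str] = Counter()
    for g in genes:
        acc.update(g.codons)
    return CodonCounts(counts=dict(acc), source=source)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RSCUProfile:
    """Relative synonymous codon usage per codon.

    RSCU_c = n_aa * x_c / sum of x over the amino acid's codons, i.e. the
    observed count divided by the count expected under uniform synonymous
    use. Codons of an amino acid absent from the source are NaN. Met and
    Trp (single-codon) carry RSCU = 1 when present, NaN when absent; they
    never enter optimality statistics.
    """

    values: Mapping[str, float]
    source: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


def rscu(counts: CodonCounts, table: CodonTable = STANDARD_CODE) -> RSCUProfile:
    """Compute RSCU for all 61 sense codons from raw counts."""
    values: dict[str, float] = {}
    for aa, codons in table.aa_to_codons.items():
        n = len(codons)
        tot = sum(counts.counts.get(c, 0) for c in codons)
        if tot == 0:
            for c in codons:
                values[c] = math.nan
        else:
            for c in codons:
                values[c] = n * counts.counts.get(c, 0) / tot
    return RSCUProfile(values=values, source=counts.source)


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CAIWeights:
    """Relative adaptiveness weights w_c over the 59 degenerate codons.

    w_c = RSCU_c / max RSCU within the amino acid, from a highly expressed
    reference set. Codons unobserved in the reference receive a small floor
    weight so the log stays defined.
    """

    w: Mapping[str, float]
    reference: str = ""
    floor: float = 0.01


def cai_weights(
    reference_counts: CodonCounts,
    table: CodonTable = STANDARD_CODE,
    floor: float = 0.01,
) -> CAIWeights:
    """Relative adaptiveness of each degenerate codon in a reference set."""
    profile = rscu(reference_counts, table)
    w: dict[str, float] = {}
    for aa in table.degenerate_aas:
        codons = table.aa_to_codons[aa]
        vals = [profile.values[c] for c in codons]
        if any(math.isnan(v) for v in vals):
            raise ReferenceCoverageError(
                f"reference set lacks amino acid {aa} entirely"
            )
        top = max(vals)
        for c, v in zip(codons, vals):
            w[c] = (v / top) if v > 0 else floor
    return CAIWeights(w=w, reference=reference_counts.source, floor=floor)


def cai(cds: CodingSequence, weights: CAIWeights) -> float:
    """Codon adaptation index: geometric mean of w over degenerate-aa codons.

    Met, Trp and stop codons are excluded. Returns NaN for a gene with no
    degenerate-amino-acid codons.
    """
    logs = [math.log(weights.w[c]) for c in cds.codons if c in weights.w]
    if not logs:
        return math.nan
    return math.exp(sum(logs) / len(logs))


def fop(
    cds: CodingSequence,
    optimal_set: Iterable[str],
    table: CodonTable = STANDARD_CODE,
) -> float:
    """Frequency of optimal codons among a gene's degenerate-aa codons."""
    optimal = set(optimal_set)
    deg = set(table.degenerate_codons)
    included = [c for c in cds.codons if c in deg]
    if not included:
        return math.nan
    return sum(c in optimal for c in included) / len(included)


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------


def read_cds_fasta(
    path: str | Path,
    table: CodonTable = STANDARD_CODE,
    skip_invalid: bool = False,
) -> dict[str, CodingSequence]:
    """Read a multi-record CDS FASTA, keeping the longest CDS per gene id.

    The gene id is the header token before the first whitespace. Records
    with ambiguous nucleotides are always dropped with a warning (codon
    identity undefined). Internal stops or bad lengths raise unless
    ``skip_invalid`` is set, in which case the gene is dropped with a
    warning.
    """
    out: dict[str, CodingSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene_id = record.id
        try:
            cds = CodingSequence.from_sequence(gene_id, str(record.seq), table)
        except AmbiguousNucleotideError as exc:
            warnings.warn(f"dropping {gene_id}: {exc}")
            continue
        except InvalidSequenceError:
            if skip_invalid:
                warnings.warn(f"dropping invalid CDS for {gene_id}")
                continue
            raise
        if gene_id not in out or len(cds) > len(out[gene_id]):
            out[gene_id] = cds
    return out
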