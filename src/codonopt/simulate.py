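"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the statistical structure of a codon-usage study in
a species with strong G3/C3 optimal-codon bias and testis-restricted
expression of male-biased genes:

* CDS sets (testis-biased, ovary-biased, unbiased, ribosomal reference)
  whose codon choice per amino-acid occurrence is drawn i.i.d. from a
  set-specific preference vector. The ribosomal reference concentrates
  extra probability mass on a designated optimal codon per amino acid;
  testis-like genes shift mass ``delta`` toward a designated primary
  non-optimal codon (ovary-like genes shift a smaller amount, producing the
  stepwise unbiased < ovary < testis gradient in non-optimal use).
* A genes x 59-tissue RPKM matrix in which sex-biased genes are expressed
  almost exclusively in their gonad (high tau) and unbiased/ribosomal
  genes are expressed broadly (low tau).
* An exact-match tRNA gene-count table whose median over the 59
  degenerate-amino-acid codons is 5, with 12 high-count and 6 zero-count
  (wobble) optimal codons and 15 high / 26 low non-optimal codons.
* A per-residue structure table: secondary-structure classes arise in
  geometric-length blocks, RSA is Beta-distributed around a class-specific
  mean, residues encoded by the designated primary non-optimal codon get an
  additive RSA offset ``mu_shift``, and disorder is RSA plus Gaussian noise
  (both clipped to [0, 1]).

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .classification import TRNATable
from .expression import ExpressionMatrix
from .genetic_code import CodingSequence, CodonTable, STANDARD_CODE

__all__ = [
    "DESIGNATED_OPTIMAL",
    "DESIGNATED_PRIMARY_NONOPT",
    "default_trna_table",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "simulate",
    "worked_example_fixture",
]


# ---------------------------------------------------------------------------
# Designated codon tables (the generator's ground truth)
# ---------------------------------------------------------------------------

# Optimal codons are G3/C3 throughout, matching the classic pattern in
# Drosophila-like genomes; designated primary non-optimal codons end in
# A3/T3/G3.
DESIGNATED_OPTIMAL: dict[str, str] = {
    "A": "GCC", "R": "CGC", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "F": "TTC", "P": "CCC", "S": "AGC",
    "T": "ACC", "Y": "TAC", "V": "GTG",
}

DESIGNATED_PRIMARY_NONOPT: dict[str, str] = {
    "A": "GCA", "R": "AGG", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGA", "H": "CAT", "I": "ATA",
    "L": "TTG", "K": "AAA", "F": "TTT", "P": "CCT", "S": "AGT",
    "T": "ACT", "Y": "TAT", "V": "GTA",
}

# Optimal codons with zero exact-match tRNA genes (wobble decoding).
_WOBBLE_OPTIMAL = frozenset({"CCC", "CGC", "TGC", "TAC", "CAC", "GTG"})

# Non-optimal codons given abundant exact-match tRNA genes. Primary
# non-optimal codons of Thr/Gly/Pro are high (paper-like pattern) while
# those of Arg/Leu/Ser/Ile stay low.
_NONOPT_HIGH_TRNA = frozenset(
    {"ACT", "GGA", "CCT", "GCG", "GGG", "CCA", "ACG", "GTT", "CTC",
     "CTT", "TCT", "TCC", "AAT", "GAT", "CAT"}
)


def default_trna_table(table: CodonTable = STANDARD_CODE) -> TRNATable:
    """Deterministic exact-match tRNA gene counts (median 5 over 59 codons)."""
    counts: dict[str, int] = {}
    optimal = set(DESIGNATED_OPTIMAL.values())
    high_opt_cycle = [14, 12, 11, 10, 9, 8]
    high_nonopt_cycle = [10, 9, 8, 7, 6, 12]
    low_cycle = [5, 5, 5, 4, 4, 3, 3, 2, 2, 1]
    i_opt = i_high = i_low = 0
    for codon in table.degenerate_codons:
        if codon in optimal:
            if codon in _WOBBLE_OPTIMAL:
                counts[codon] = 0
            else:
                counts[codon] = high_opt_cycle[i_opt % len(high_opt_cycle)]
                i_opt += 1
        elif codon in _NONOPT_HIGH_TRNA:
            counts[codon] = high_nonopt_cycle[i_high % len(high_nonopt_cycle)]
            i_high += 1
        else:
            counts[codon] = low_cycle[i_low % len(low_cycle)]
            i_low += 1
    # Met and Trp carry plausible counts but never enter classification.
    counts["ATG"] = 10
    counts["TGG"] = 8
    return TRNATable(counts=counts, species="synthetic")


def _default_aa_freqs(table: CodonTable) -> dict[str, float]:
    freqs = {aa: (1.0 - 0.04) / 18.0 for aa in table.degenerate_aas}
    freqs["M"] = 0.02
    freqs["W"] = 0.02
    return freqs


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Defaults follow the reference study's observed scale: gene-set sizes
    916/258/605, median CDS lengths 273/498/269 codons, 59 tissues, a
    testis preference shift of 0.15 toward the primary non-optimal codon,
    and an RSA offset of 0.10 for residues encoded by that codon.
    """

    seed: int = 0
    n_genes: dict = field(
        default_factory=lambda: {
            "testis": 916, "ovary": 258, "unbiased": 605, "ribosomal": 150,
        }
    )
    median_codons: dict = field(
        default_factory=lambda: {
            "testis": 273, "ovary": 498, "unbiased": 269, "ribosomal": 350,
        }
    )
    length_sigma: float = 0.35
    min_codons: int = 60
    aa_freqs: dict | None = None
    dirichlet_conc: float = 50.0
    opt_bias_background: float = 0.20
    opt_bias_ribosomal: float = 0.60
    delta_testis: float = 0.15
    delta_ovary: float = 0.05
    # expression model
    n_tissues: int = 59
    focal_log_median: float = np.log(300.0)
    focal_sigma: float = 0.6
    frac_sex_specific: float = 0.79
    # non-focal tissue levels per sex-biased class; testis-biased genes are
    # nearly testis-restricted (tau ~ 0.95) while ovary-biased genes leak
    # into other tissues (tau ~ 0.85), emulating the observed gradient
    nonfocal_log_median: dict = field(
        default_factory=lambda: {"testis": np.log(8.0), "ovary": np.log(40.0)}
    )
    baseline_log_median: float = np.log(0.5)
    baseline_sigma: float = 1.0
    broad_log_median: float = np.log(100.0)
    broad_sigma: float = 0.8
    # RSA model
    ss_mean: dict = field(
        default_factory=lambda: {"strand": 0.13, "helix": 0.34, "coil": 0.53}
    )
    ss_concentration: float = 8.0
    ss_block_mean: dict = field(
        default_factory=lambda: {"coil": 8.0, "helix": 10.0, "strand": 5.0}
    )
    mu_shift: float = 0.10
    disorder_sd: float = 0.2


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    optimal: Mapping[str, str]
    primary_nonopt: Mapping[str, str]
    gene_class: Mapping[str, str]
    delta_testis: float
    delta_ovary: float
    mu_shift: float


@dataclass
class SimResult:
    cds: dict[str, dict[str, CodingSequence]]  # set label -> gene -> CDS
    expression: ExpressionMatrix
    trna: TRNATable
    structure: pd.DataFrame
    truth: GroundTruth
    config: SimConfig

    def all_cds(self) -> dict[str, CodingSequence]:
        out: dict[str, CodingSequence] = {}
        for genes in self.cds.values():
            out.update(genes)
        return out

    def write(self, outdir: str | Path) -> None:
        """Emit the file dialects the pipeline reads, plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "cds.fasta", "w") as fh:
            for label in sorted(self.cds):
                for gene_id in sorted(self.cds[label]):
                    seq = "".join(self.cds[label][gene_id].codons) + "TAA"
                    fh.write(f">{gene_id} set={label}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")
        self.expression.values.to_csv(
            outdir / "expression.tsv", sep="\t", index_label="gene_id"
        )
        rows = sorted(self.trna.counts.items())
        pd.DataFrame(rows, columns=["codon", "count"]).to_csv(
            outdir / "trna.tsv", sep="\t", index=False
        )
        self.structure.to_csv(outdir / "structure.tsv", sep="\t", index=False)
        manifest = {
            "seed": self.config.seed,
            "delta_testis": float(self.truth.delta_testis),
            "delta_ovary": float(self.truth.delta_ovary),
            "mu_shift": float(self.truth.mu_shift),
            "optimal": dict(self.truth.optimal),
            "primary_nonopt": dict(self.truth.primary_nonopt),
            "gene_class": dict(self.truth.gene_class),
        }
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Codon-preference machinery
# ---------------------------------------------------------------------------


def _baseline_preferences(
    rng: np.random.Generator, table: CodonTable, conc: float
) -> dict[str, np.ndarray]:
    """One near-uniform Dirichlet baseline per amino acid, shared by every
    gene set so that a zero-shift world is a true null for contrasts."""
    return {
        aa: rng.dirichlet(np.full(len(table.aa_to_codons[aa]), conc))
        for aa in table.degenerate_aas
    }


def _set_preferences(
    baselines: Mapping[str, np.ndarray],
    table: CodonTable,
    opt_bias: float,
    delta: float,
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-amino-acid codon sampling probabilities for one gene set.

    ``opt_bias`` mass is moved onto the designated optimal codon and then
    ``delta`` mass onto the designated primary non-optimal codon.
    """
    prefs = {}
    for aa in table.degenerate_aas:
        codons = table.aa_to_codons[aa]
        p = baselines[aa] * (1.0 - opt_bias)
        p[codons.index(DESIGNATED_OPTIMAL[aa])] += opt_bias
        if delta > 0:
            p = p * (1.0 - delta)
            p[codons.index(DESIGNATED_PRIMARY_NONOPT[aa])] += delta
        prefs[aa] = (codons, p / p.sum())
    # Met and Trp have a single codon each.
    prefs["M"] = (("ATG",), np.array([1.0]))
    prefs["W"] = (("TGG",), np.array([1.0]))
    return prefs


def _sample_cds_set(
    rng: np.random.Generator,
    label: str,
    n_genes: int,
    median_codons: float,
    sigma: float,
    min_codons: int,
    aa_freqs: Mapping[str, float],
    prefs: Mapping[str, tuple[tuple[str, ...], np.ndarray]],
) -> dict[str, CodingSequence]:
    """Draw one gene set; codon choice is i.i.d. per amino-acid occurrence."""
    aas = np.array(sorted(aa_freqs))
    p_aa = np.array([aa_freqs[a] for a in aas])
    p_aa = p_aa / p_aa.sum()
    lengths = np.maximum(
        min_codons,
        np.rint(
            np.exp(rng.normal(np.log(median_codons), sigma, size=n_genes))
        ).astype(int),
    )
    total = int(lengths.sum())
    flat_aa = rng.choice(aas, size=total, p=p_aa)
    flat_codon = np.empty(total, dtype="U3")
    for aa in aas:
        idx = np.flatnonzero(flat_aa == aa)
        if idx.size == 0:
            continue
        codons, p = prefs[aa]
        flat_codon[idx] = rng.choice(np.array(codons), size=idx.size, p=p)
    genes: dict[str, CodingSequence] = {}
    start = 0
    for i, length in enumerate(lengths):
        gene_id = f"{label}_{i:04d}"
        body = tuple(flat_codon[start : start + length])
        genes[gene_id] = CodingSequence(gene_id=gene_id, codons=("ATG",) + body)
        start += length
    return genes


# ---------------------------------------------------------------------------
# Expression machinery
# ---------------------------------------------------------------------------


def _expression_matrix(
    rng: np.random.Generator,
    cfg: SimConfig,
    gene_class: Mapping[str, str],
) -> ExpressionMatrix:
    tissues = ["testis", "ovary"] + [
        f"tissue{i:02d}" for i in range(3, cfg.n_tissues + 1)
    ]
    genes = sorted(gene_class)
    n = len(genes)
    values = np.exp(
        rng.normal(cfg.baseline_log_median, cfg.baseline_sigma, size=(n, cfg.n_tissues))
    )
    df = pd.DataFrame(values, index=genes, columns=tissues)
    for i, g in enumerate(genes):
        klass = gene_class[g]
        if klass in ("testis", "ovary"):
            df.iloc[i, :] = np.exp(
                rng.normal(
                    cfg.nonfocal_log_median[klass], cfg.baseline_sigma,
                    size=cfg.n_tissues,
                )
            )
            focal = float(np.exp(rng.normal(cfg.focal_log_median, cfg.focal_sigma)))
            if rng.random() < cfg.frac_sex_specific:
                minor = float(np.exp(rng.normal(np.log(0.3), 0.7)))
            else:
                minor = float(np.exp(rng.normal(np.log(10.0), 0.7)))
            minor = min(minor, focal / 5.0)  # keep the designed fold-bias
            major_t, minor_t = ("testis", "ovary") if klass == "testis" else (
                "ovary", "testis"
            )
            df.iloc[i, df.columns.get_loc(major_t)] = focal
            df.iloc[i, df.columns.get_loc(minor_t)] = minor
        else:  # unbiased and ribosomal genes: broad expression
            broad = np.exp(
                rng.normal(cfg.broad_log_median, cfg.broad_sigma, size=cfg.n_tissues)
            )
            gonads = np.exp(rng.normal(np.log(200.0), 0.5))
            ratio = np.exp(rng.normal(0.0, 0.3))
            df.iloc[i, :] = broad
            df.iloc[i, df.columns.get_loc("testis")] = gonads * ratio
            df.iloc[i, df.columns.get_loc("ovary")] = gonads / ratio
    return ExpressionMatrix(values=df, focal=("testis", "ovary"))


# ---------------------------------------------------------------------------
# Structure machinery
# ---------------------------------------------------------------------------


def _ss_blocks(rng: np.random.Generator, length: int, block_mean: Mapping[str, float]):
    classes = ("coil", "helix", "strand")
    out = np.empty(length, dtype="U6")
    pos = 0
    current = classes[rng.integers(3)]
    while pos < length:
        block = int(rng.geometric(1.0 / block_mean[current]))
        end = min(length, pos + block)
        out[pos:end] = current
        pos = end
        others = [c for c in classes if c != current]
        current = others[rng.integers(2)]
    return out


def _structure_table(
    rng: np.random.Generator,
    cfg: SimConfig,
    cds_sets: Mapping[str, Mapping[str, CodingSequence]],
    table: CodonTable,
) -> pd.DataFrame:
    primary = set(DESIGNATED_PRIMARY_NONOPT.values())
    frames = []
    for label in sorted(cds_sets):
        if label == "ribosomal":
            continue  # structure is analyzed for the study sets only
        for gene_id in sorted(cds_sets[label]):
            cds = cds_sets[label][gene_id]
            L = len(cds)
            ss = _ss_blocks(rng, L, cfg.ss_block_mean)
            means = np.array([cfg.ss_mean[s] for s in ss])
            a = means * cfg.ss_concentration
            b = (1.0 - means) * cfg.ss_concentration
            rsa = rng.beta(a, b)
            codons = np.array(cds.codons)
            shift_mask = np.isin(codons, list(primary))
            rsa = np.clip(rsa + cfg.mu_shift * shift_mask, 0.0, 1.0)
            disorder = np.clip(rsa + rng.normal(0.0, cfg.disorder_sd, size=L), 0.0, 1.0)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_id,
                        "position": np.arange(1, L + 1),
                        "aa": [table.codon_to_aa[c] for c in cds.codons],
                        "rsa": np.round(rsa, 6),
                        "disorder": np.round(disorder, 6),
                        "ss_class": ss,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------


def simulate(config: SimConfig | None = None, table: CodonTable = STANDARD_CODE) -> SimResult:
    """Generate all pipeline inputs for one synthetic world."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    aa_freqs = cfg.aa_freqs or _default_aa_freqs(table)

    deltas = {
        "testis": cfg.delta_testis,
        "ovary": cfg.delta_ovary,
        "unbiased": 0.0,
        "ribosomal": 0.0,
    }
    biases = {
        "testis": cfg.opt_bias_background,
        "ovary": cfg.opt_bias_background,
        "unbiased": cfg.opt_bias_background,
        "ribosomal": cfg.opt_bias_ribosomal,
    }
    baselines = _baseline_preferences(rng, table, cfg.dirichlet_conc)
    cds_sets: dict[str, dict[str, CodingSequence]] = {}
    for label in ("testis", "ovary", "unbiased", "ribosomal"):
        n = cfg.n_genes.get(label, 0)
        if n <= 0:
            cds_sets[label] = {}
            continue
        prefs = _set_preferences(baselines, table, biases[label], deltas[label])
        cds_sets[label] = _sample_cds_set(
            rng,
            label,
            n,
            cfg.median_codons.get(label, 273),
            cfg.length_sigma,
            cfg.min_codons,
            aa_freqs,
            prefs,
        )

    gene_class = {
        g: label for label, genes in cds_sets.items() for g in genes
    }
    expression = _expression_matrix(rng, cfg, gene_class)
    structure = _structure_table(rng, cfg, cds_sets, table)
    truth = GroundTruth(
        optimal=dict(DESIGNATED_OPTIMAL),
        primary_nonopt=dict(DESIGNATED_PRIMARY_NONOPT),
        gene_class=gene_class,
        delta_testis=cfg.delta_testis,
        delta_ovary=cfg.delta_ovary,
        mu_shift=cfg.mu_shift,
    )
    return SimResult(
        cds=cds_sets,
        expression=expression,
        trna=default_trna_table(table),
        structure=structure,
        truth=truth,
        config=cfg,
    )


def worked_example_fixture(seed: int = 20240613) -> SimResult:
    """A tiny fixed dataset (12 genes, 4 tissues) for worked examples.

    Regenerates bit-identically from its constant seed.
    """
    cfg = SimConfig(
        seed=seed,
        n_genes={"testis": 3, "ovary": 3, "unbiased": 3, "ribosomal": 3},
        median_codons={"testis": 80, "ovary": 90, "unbiased": 80, "ribosomal": 100},
        n_tissues=4,
    )
    return simulate(cfg)
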