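"""File interfaces, pipeline configuration, and the end-to-end driver.

All tables are TSV (tab-separated, header row, UTF-8, '.' decimal). Gene
identifiers are opaque strings; the FASTA header token before the first
whitespace is the gene id.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classification import (
    classify_codons,
    read_trna_table,
    write_classification,
)
from .contrasts import (
    contrast,
    extreme_use_table,
    identify_primary_nonoptimal,
    rscu_matrix,
)
from .expression import ExpressionMatrix, classify_sex_bias, subclass
from .genetic_code import concatenate_counts, read_cds_fasta
from .structure import (
    bin_rsa_comparison,
    gene_structure_summary,
    join_cds_structure,
    read_structure_table,
    rsa_by_codon,
    rsa_disorder_correlation,
    ss_composition,
)

__all__ = ["PipelineConfig", "run_pipeline", "read_expression_tsv"]

logger = logging.getLogger("codonopt")


def read_expression_tsv(
    path: str | Path, focal: tuple[str, str] = ("testis", "ovary")
) -> ExpressionMatrix:
    """Read a gene x tissue RPKM TSV (first column: gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, focal=focal)


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for a full run."""

    fasta: str = ""
    expression: str = ""
    trna: str = ""
    structure: str = ""  # optional; structure stages skip when empty/missing
    ribosomal_ids: str = ""  # optional text file, one reference gene id per line
    outdir: str = "codonopt_out"
    focal: tuple[str, str] = ("testis", "ovary")
    min_rpkm: float = 100.0
    fold: float = 5.0
    extreme_rscu: float = 1.5
    length_cutoff: int = 272
    bin_low: float = 50.0
    bin_high: float = 60.0
    cai_floor: float = 0.01
    pseudocount: float = 0.01
    sex_specific_floor: float = 1.0
    equal_var: bool = False
    p_adjust: str = "none"
    log_transform_tau: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_low >= self.bin_high:
            raise ValueError("Percent-Non-opt bins must be ordered")
        for name in ("min_rpkm", "fold", "extreme_rscu", "length_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "focal" in raw:
            raw["focal"] = tuple(raw["focal"])
        return cls(**raw)


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    filehandler = logging.FileHandler(outdir / "run.log", mode="w")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (stream, filehandler):
        h.setFormatter(fmt)
        logger.addHandler(h)


def run_pipeline(config: PipelineConfig) -> dict:
    """Classify codons, call sex-bias classes, run contrasts and structure
    analysis, and write the report bundle. Returns the in-memory results."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("codonopt %s starting; seed=%d", __version__, config.seed)
    logger.info("config: %s", json.dumps(asdict(config)))

    cds = read_cds_fasta(config.fasta, skip_invalid=True)
    expr = read_expression_tsv(config.expression, focal=config.focal)
    trna = read_trna_table(config.trna)
    shared = set(cds) & set(expr.values.index)
    if not shared:
        raise ValueError("no gene ids shared between FASTA and expression matrix")
    logger.info("%d genes with both CDS and expression", len(shared))

    # --- sex-bias classes -------------------------------------------------
    records = classify_sex_bias(
        expr,
        min_rpkm=config.min_rpkm,
        fold=config.fold,
        pseudocount=config.pseudocount,
        sex_specific_floor=config.sex_specific_floor,
        log_transform_tau=config.log_transform_tau,
    )
    records = subclass(records, expr, cds, length_cutoff=config.length_cutoff)
    records.to_csv(outdir / "gene_classes.tsv", sep="\t", index_label="gene_id")

    sets = {
        "testis": {g for g in shared if records.loc[g, "sex_class"] == "testis_biased"},
        "ovary": {g for g in shared if records.loc[g, "sex_class"] == "ovary_biased"},
        "unbiased": {g for g in shared if records.loc[g, "sex_class"] == "unbiased"},
    }
    for label, ids in sets.items():
        logger.info("%s-biased set: %d genes", label, len(ids))

    # --- a-priori codon classification -----------------------------------
    if config.ribosomal_ids:
        ribo_ids = {
            line.strip()
            for line in Path(config.ribosomal_ids).read_text().splitlines()
            if line.strip()
        }
        ribo_ids &= set(cds)
    else:
        ribo_ids = {g for g in cds if g.startswith("ribosomal")}
    if not ribo_ids:
        raise ValueError("no ribosomal reference genes found")
    ribo_counts = concatenate_counts(
        (cds[g] for g in sorted(ribo_ids)), source="ribosomal"
    )
    all_counts = concatenate_counts(cds.values(), source="all")
    cls = classify_codons(ribo_counts, all_counts, trna)
    write_classification(cls, outdir / "codon_classification.tsv")

    # --- contrasts and primary non-optimal calls --------------------------
    matrices = {
        label: rscu_matrix({g: cds[g] for g in sorted(ids)})
        for label, ids in sets.items()
        if ids
    }
    results: dict = {
        "records": records,
        "classification": cls,
        "matrices": matrices,
    }
    if all(k in matrices for k in ("testis", "ovary", "unbiased")):
        c_to = contrast(
            matrices["testis"], matrices["ovary"],
            equal_var=config.equal_var, adjust=config.p_adjust,
        )
        c_tu = contrast(
            matrices["testis"], matrices["unbiased"],
            equal_var=config.equal_var, adjust=config.p_adjust,
        )
        c_to.to_csv(outdir / "contrast_testis_ovary.tsv", sep="\t")
        c_tu.to_csv(outdir / "contrast_testis_unbiased.tsv", sep="\t")
        primary = identify_primary_nonoptimal(c_to, c_tu, cls)
        primary.to_csv(outdir / "primary_nonoptimal.tsv", sep="\t")
        results.update(contrast_TO=c_to, contrast_TU=c_tu, primary=primary)

        extreme_rows = []
        for aa, codon in primary["primary"].dropna().items():
            fractions, pairs = extreme_use_table(
                matrices, codon, threshold=config.extreme_rscu
            )
            for label, row in fractions.iterrows():
                extreme_rows.append(
                    {"aa": aa, "codon": codon, "gene_set": label, **row.to_dict()}
                )
        pd.DataFrame(extreme_rows).to_csv(
            outdir / "extreme_use.tsv", sep="\t", index=False
        )
    else:
        logger.warning("missing gene sets; contrasts skipped")
        primary = None

    # --- structure stages (optional) --------------------------------------
    if config.structure and Path(config.structure).exists():
        residues = read_structure_table(config.structure)
        summaries = gene_structure_summary(
            {g: cds[g] for g in shared if g in cds}, residues, cls
        )
        summaries.to_csv(outdir / "gene_structure.tsv", sep="\t")
        per_bin, bin_pairs = bin_rsa_comparison(summaries)
        per_bin.to_csv(outdir / "rsa_by_bin.tsv", sep="\t")
        bin_pairs.to_csv(outdir / "rsa_bin_tests.tsv", sep="\t", index=False)
        comp, _ = ss_composition(residues)
        comp.to_csv(outdir / "ss_composition.tsv", sep="\t")
        corr = rsa_disorder_correlation(residues)

        joined = []
        testis_ids = sets["testis"]
        for g in sorted(testis_ids):
            sub = residues[residues["gene_id"] == g]
            if len(sub) == len(cds[g]):
                joined.append(join_cds_structure(cds[g], sub))
        sign_report = {}
        if joined and primary is not None:
            testis_residues = pd.concat(joined, ignore_index=True)
            per_aa, sign = rsa_by_codon(testis_residues, cls, primary)
            per_aa.to_csv(outdir / "rsa_by_codon.tsv", sep="\t")
            if sign is not None:
                sign_report = {
                    "n_higher_nonopt": int(sign.statistic),
                    "n_compared": int(sign.n[0]),
                    "p_value": sign.p_value,
                }
            results.update(rsa_by_codon=per_aa, sign_test=sign)
        report = {
            "rsa_disorder_spearman_rho": corr.statistic,
            "rsa_disorder_spearman_p": corr.p_value,
            "sign_test": sign_report,
        }
        with open(outdir / "structure_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        results.update(summaries=summaries, rsa_bins=per_bin)
    else:
        logger.warning("structure table absent; structure stages skipped")

    logger.info("pipeline finished; reports in %s", outdir)
    return results
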