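# Methods

This note documents the models, conventions and numerical choices behind
`codonopt`, in the spirit of a statistical-software methods appendix.

## The genetic-code domain

All optimality statistics operate on the 59 sense codons of the 18
degenerate amino acids. Met and Trp are single-codon amino acids: their
RSCU is reported as 1 when present, but they are excluded from CAI's
geometric mean, from Fop's denominator, and from Percent-Non-opt, because a
codon with no synonymous alternative carries no information about choice.
Stop codons never enter any statistic; a terminal stop is stripped at CDS
construction and an internal stop is a hard error (downgradable to
warn-and-drop for batch FASTA input). Sequences containing ambiguous
nucleotides are dropped with a warning since the codon identity is
undefined. When a FASTA file carries several records per gene id
(isoforms), the longest CDS is kept.

## Codon-usage statistics

* **RSCU** follows the classic definition: observed count divided by the
  count expected under uniform synonymous use,
  `RSCU_c = n * x_c / sum(x)` within the amino-acid family. Codons of an
  amino acid absent from the source are NA (not 0): absence of evidence is
  not evidence of avoidance.
* **CAI** uses relative adaptiveness `w_c = RSCU_c / max RSCU` from a
  highly expressed reference. Codons unobserved in the reference receive a
  floor weight of 0.01 (the long-standing practice that keeps `log w`
  defined); the floor is configurable. A reference lacking an entire amino
  acid is rejected as inadequate rather than silently patched.
* **Fop** counts optimal codons over degenerate-amino-acid codons only.

## A-priori codon classification

Optimal codons are called per amino acid as the argmax of
`ΔRSCU = RSCU_reference − RSCU_background` computed on concatenated counts
(both profiles sum to the degeneracy per amino acid, so the deltas sum to
zero). Ties break to the lexicographically first codon and are flagged
rather than hidden; an amino acid whose best delta is not positive is still
assigned its argmax but flagged `no_positive_optimal`.

tRNA stratification uses exact-match tRNA gene counts. The high/low
threshold is the median count over the 59 degenerate-amino-acid codons
(not all 61 — the classification domain); counts strictly greater than the
median are high, equal-to-median counts are low. That boundary side is a
convention the source data do not dictate; it is fixed and documented here.
Wobble status is reserved for optimal codons with zero exact matches —
the four-category scheme names no non-optimal wobble class, so zero-count
non-optimal codons fold into the low class. An optimal codon with a
few-but-nonzero matches (absent from the reference organism's data) would
receive an explicit out-of-scheme `Opt_low-tRNAs` label rather than a
misleading one.

## Sex-bias classes and tau

A gene is testis-biased when testis ≥ 100 RPKM and testis/ovary ≥ 5
(ovary-biased symmetrically), unbiased when the fold-bias is < 5 and at
least one gonad reaches 100 RPKM, otherwise excluded. All printed
thresholds (≥ 100, ≥ 5-fold, ≥ 200, ≥ 272 codons) are inclusive as
written. A pseudocount of 0.01 RPKM guards the ratio, but it is applied
only when a focal value is exactly zero: applying it unconditionally would
push genes sitting exactly on a printed threshold (e.g. 100 vs 20 RPKM,
exactly 5-fold) off their boundary. Sex-biased genes whose minor gonad
falls below 1 RPKM are additionally marked sex-specific; the 1-RPKM floor
is a configurable convention.

tau is computed on untransformed RPKM over the supplied tissue panel
(`log2(x+1)` available as an option); it is scale-invariant per gene, 0 for
uniform expression and 1 for single-tissue expression, and NA for an
all-zero row.

## Contrasts and primary non-optimal codons

Per-gene RSCU matrices use pairwise deletion: a gene contributes to a
codon's contrast only when it uses the amino acid at all. Contrasts report
the difference of per-gene means with a two-sided Welch t-test (Student's
available by flag); Welch is the robust default when variance equality is
unverifiable. No multiple-testing correction is applied by default — the
per-codon p-values are reported raw — with Benjamini–Hochberg as an option.
A codon with fewer than two contributing genes in either set keeps its
delta but gets NA test results.

The primary non-optimal codon per amino acid is the argmax of the
testis-versus-unbiased delta among the amino acid's non-optimal codons,
called only when the testis-versus-ovary delta is also positive (the
unbiased contrast ranks because its larger gene set gives more power; the
ovary contrast acts as a sign gate). A runner-up whose delta reaches 80% of
the primary's is reported as secondary; the 80% threshold is a package
convention exposed in the call signature. Extreme use of a codon is the
fraction of genes with RSCU ≥ 1.5 (inclusive), compared across gene sets
with 2×2 chi-square tests.

## Structure analysis

Per-residue tables (gene, 1-based position, amino acid, RSA, disorder,
secondary structure) are validated against the CDS: lengths must match and
every codon must translate to the recorded residue. Eight-class secondary
structure codes collapse to three via H/G/I → helix, E/B → strand,
rest → coil.

Percent-Non-opt is the share of a gene's degenerate-amino-acid codons that
are non-optimal, binned at ≤ 50 (low), 50–60 (moderate), > 60 (high).
Gene-wide RSA uses the mean over residues (median available); bins are
compared with two-sided Mann–Whitney U tests. The per-amino-acid
codon-class comparison uses means with standard errors, and the overall
direction is tested with an exact binomial sign test (two-sided by doubling
the smaller tail, capped at 1) — with only 18 paired comparisons a normal
approximation would be inappropriate. Amino acids lacking residues under
either codon class are excluded from the sign test and reported; the test
is suppressed below 5 comparable amino acids.

"Ranked ANOVA" is provided as Kruskal–Wallis with Dunn's post hoc; Dunn's
pairwise z is computed from pooled mean ranks with the standard tie
correction, unadjusted by default (Bonferroni/BH optional).

## The synthetic-data generator

The generator emulates the statistical structure the analysis is designed
to detect, with full ground truth:

* **Codon choice** is i.i.d. per amino-acid occurrence from a set-specific
  preference vector — positional autocorrelation (translational ramps) is
  deliberately out of scope because every downstream statistic is
  occurrence-level. A single near-uniform Dirichlet baseline (concentration
  50) is drawn per world and shared by all gene sets, so a zero-shift world
  is a true null for contrasts. Study sets put 0.20 extra mass on the
  designated optimal codon (background codon bias), the ribosomal reference
  0.60 (strong optimization); testis-like genes then shift δ = 0.15 of mass
  onto the designated primary non-optimal codon and ovary-like genes 0.05,
  producing the stepwise unbiased < ovary < testis gradient of non-optimal
  use.
* **Set sizes and lengths** default to the reference study's scale: 916
  testis-, 258 ovary-biased and 605 unbiased genes with log-normal CDS
  lengths of median 273/498/269 codons (σ = 0.35 on the log scale), plus
  150 ribosomal reference genes.
* **Designated codons**: optimal codons are G3/C3 throughout; primary
  non-optimal codons end in A3/T3/G3, so recovering them cannot be
  explained by a single third-position nucleotide preference. The default
  tRNA table gives 12 optimal codons high exact-match counts (8–14), 6
  optimal codons zero (wobble), 15 non-optimal codons high and 26 low, with
  median 5 over the 59 codons.
* **Expression** spans 59 tissues. Sex-biased genes express at log-normal
  median 300 RPKM in their gonad; 79% are sex-specific (minor gonad at
  median 0.3 RPKM), the rest have a detectable minor gonad capped at
  focal/5 to preserve the designed fold-bias. Non-focal tissues sit at
  median 8 RPKM for testis-biased and 40 for ovary-biased genes, and
  unbiased genes are broadly expressed (median 100), which yields realized
  median tau around 0.96 / 0.87 / 0.78 — the stepwise specificity gradient
  of the real tissue panels.
* **Structure**: secondary-structure classes arise in geometric-length
  blocks (mean 8/10/5 residues for coil/helix/strand — only the marginal
  fractions matter downstream); RSA is Beta-distributed with means 0.13 /
  0.34 / 0.53 for strand/helix/coil at concentration 8; residues encoded by
  a designated primary non-optimal codon get +0.10 RSA (clipped to [0,1]);
  disorder is RSA plus N(0, 0.2) noise, clipped.

Everything is a deterministic function of the seed; the same seed produces
byte-identical output files.

**What the generator does not emulate.** Real genomes have correlated
amino-acid composition, isochore/GC structure, positional codon
autocorrelation, alternative splicing, and expression matrices with
correlated tissues; RSA predictors have structured (not Beta) error and
gene-level correlation between composition and structure. Passing
recovery tests therefore demonstrate that the statistics detect the effects
they target at realistic effect sizes and sample sizes — not that any
particular real dataset will show those effects.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the recovery experiments at
300 genes per set (primary-codon recovery), 160 genes × 20 replicates (RSA
direction), and 34 zero-shift worlds of 60 + 60 genes (≈ 2,000 per-codon
tests for type-I calibration) — sizes at which the designed effects are
comfortably detectable while a full run stays around a minute on one CPU.
Exact conventions worth restating: RSCU family sums are checked to 1e-9;
argmax ties break lexicographically and are flagged; degenerate zero-
variance contrasts report t = 0, p = 1; the chi-square uses no Yates
correction and warns below expected counts of 5; all thresholds are
inclusive as printed.

## Known limitations

* The primary-codon call uses a fixed gate (both deltas positive, ranking
  by the unbiased contrast); datasets where the two contrasts genuinely
  disagree will return no call for the affected amino acid rather than
  adjudicate.
* CAI's floor weight makes gene-level CAI mildly sensitive to reference
  sparsity for very rare codons.
* The per-codon t-tests treat genes as independent; gene families or
  shared evolutionary history are not modeled (no phylogenetic
  correction).
* tau on untransformed RPKM is dominated by the maximum tissue; the log
  option changes absolute values and should not be mixed across analyses.
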