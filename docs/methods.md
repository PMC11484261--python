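# Methods

## Problem and model

Single-cell immune profiling assembles, per cell barcode, a set of V(D)J
contigs with gene calls and QC flags. The analysis question is how many
T cells carry more than one functional receptor chain per locus (dual-TCR /
allelically included cells), how those cells are distributed across pairing
classes, clones and T-cell subsets, and whether their proportions shift
between patient groups (for the motivating application: Kawasaki-disease
patients before and after IVIG treatment, versus healthy controls).

The pipeline is deliberately deterministic and rule-based; the only model
fitting is the classical test battery at the end.

### Contig QC

Four exclusion rules are applied in a fixed order, each contig charged to
the first rule it violates: not a cell barcode; not a high-confidence
assembly; locus outside {TRA, TRB} (γδ chains and multi-locus artifacts);
not productive (out of frame, stop codon, or undetermined). The order only
affects which rule a multiply-failing contig is charged to, never whether it
is removed. Per-rule drop counts are carried in a `QCReport` whose balance
(input = retained + Σ drops) is asserted on every run, so denominators are
auditable. An optional minimum-UMI rule exists but defaults to 0: secondary
chains of genuine dual-receptor cells are systematically lower-UMI, and any
uncited UMI dominance filter would bias the quantity under study toward
zero.

### Chain identity

A chain is identified by (locus, V gene, J gene, CDR3). Three resolutions
are supported:

- `nt` (default) — nucleotide CDR3. Distinguishes convergent rearrangements
  that share an amino-acid junction, and distinguishes rearrangements that
  share V/J but differ in junction; this is the strictest identity that the
  input reliably provides.
- `aa` — amino-acid CDR3, for comparison with amino-acid-level repertoire
  tools.
- `gene` — V/J pair only (coarse; merges distinct rearrangements).

The D gene is excluded everywhere: it is absent on TRA, unreliably called on
TRB, and the junction string already encodes it. The C gene is ignored for
identity (contigs differing only in constant-gene call describe the same
rearrangement). Allele suffixes (`*01`) are stripped at read time; all
reported gene usage is gene-level. Gene names are otherwise taken verbatim,
with no registry validation — public datasets contain names absent from or
deprecated in IMGT, and silently renaming them would make results
untraceable.

Duplicate contigs for the same chain within a barcode (same identity key)
are collapsed with UMIs summed; contigs that survive QC but lack V, J or
CDR3 cannot form an identity key and are counted and dropped with a warning.

### Pairing taxonomy

With *a* distinct α chains and *b* distinct β chains, a paired cell
(a ≥ 1 and b ≥ 1) maps to: (1,1) single; (1,2) dual-β; (2,1) dual-α;
(2,2) dual at both loci; anything with a ≥ 3 or b ≥ 3 to the residual
"others" class. The five classes partition the paired cells, which is
asserted on every summary. "Others" counts toward the dual total: it is a
multi-receptor class, and per-sample arithmetic (single + dual = paired)
only balances when it does. Cells lacking a chain at either locus are
excluded before classification — a cell with one detected locus cannot be
assigned a pairing class, only a dropout state.

Percentages are displayed half-up-rounded to two decimals; every statistic
consumes unrounded values. The bundled published cohort table
(`dualtcr.reference`) reproduces each printed percentage to within ±0.01 of
the count-derived value (a few printed cells appear truncated rather than
rounded, hence the band).

### Clonotypes and expansion

Two cells belong to the same clonotype when their *entire* chain-key sets
are identical (`full_set`, default). For dual cells this is the only
definition under which a clone is unambiguous; a `beta_only` alternative
(identical β chain sets) is provided for comparison with bulk-style β-chain
clonotyping. Clonotypes are called within a sample and within a receptor
class, so single-cell and dual-cell expansion are reported independently;
pooling across timepoints is deliberately not done — a "clone" spanning two
blood draws is a different object and would need explicit justification.
Clonal expansion means clonotype size ≥ 2. Clonotype output order (sample,
class, size-descending, then chain keys) is canonical, making clonotype
calling invariant under cell-order permutation.

### Gene usage

Usage is counted per chain, not per cell: a dual-α cell contributes two TRAV
observations. This is what makes single-versus-dual usage comparisons well
defined — counting cells would force an arbitrary choice of "the" chain for
a dual cell. Frequencies are normalized within each
(family, receptor class, group) stratum and sum to 1 in every non-empty
stratum.

### Subset integration

Subset labels (the seven-way naive/CM/EM CD4/CD8 + Treg split) are consumed
as an external table keyed by (sample, barcode); producing them requires
transcriptome clustering and marker annotation, which is out of scope here.
The join is inner, with unmatched counts reported on both sides; unknown
subset labels are a hard error because they almost always indicate a typo'd
annotation file rather than a new subset. Composition tables are produced in
both orientations: class proportions within each subset, and the
distribution of each class across subsets.

### Statistics

Welch's t (default; Student's available), paired t, Pearson χ² without
continuity correction, and one-way ANOVA are computed from their textbook
formulas; tail probabilities come from the regularized incomplete
beta/gamma functions (`scipy.special.stdtr`, `chdtrc`, `fdtrc`). Tests are
two-sided. No multiple-testing correction is applied by default (single
planned comparisons at α = 0.05); Benjamini–Hochberg adjustment is available
for callers testing many strata. Degenerate inputs raise rather than return
NaN: zero variance in both groups, constant-shift paired differences, a zero
row/column margin in a contingency table, and all-constant ANOVA groups are
all undefined and reported as such. Identical paired samples (all
differences exactly zero) return t = 0, p = 1 — no evidence, not an error.
The test suite cross-checks a 20-case random battery against scipy.stats to
1e-6 and verifies empirical type-I error in [0.04, 0.06] at 10,000 null
replicates per test.

## Synthetic data

The generator emulates the statistical structure of a peripheral-blood αβ
scTCR-seq sample, not its sequence biology:

- **Pairing mixture** — each clonotype draws a pairing class from a
  configurable probability vector. The default vector (87% single; dual mass
  split 27.7 / 57.7 / 10.5 / 4.1% across dual-β / dual-α / double-dual /
  others) matches the published cohort-wide composition, dual-α dominant.
- **Clones** — clonotype sizes follow a geometric law (default singletons;
  the cohort preset uses p = 0.9, mean clone size ≈ 1.1) plus explicitly
  planted clones; every clonotype receives a unique chain set, so
  ground-truth clone sizes are exact.
- **Chains** — V/J genes drawn from weighted pools (IMGT-style names,
  power-law weights by default, so usage is biased as in real repertoires);
  CDR3nt strings start TGT/TGC with length a multiple of 3 in 30–60 nt.
  Cosmetically realistic; no recombination-machinery or junction-insertion
  modeling is claimed.
- **Noise** — rates are fractions of the paired-cell count: ambient non-cell
  barcodes, low-confidence extra contigs, non-productive contigs (half
  flagged false, half undetermined), duplicate contigs with split UMIs,
  single-locus (unpaired) cells, and optional barcode doublets (two cells
  merged under one barcode — the main real-world confounder of dual-TCR
  calls, off by default). Every noise contig that a QC rule should remove is
  recorded in the ground truth under that rule, so drop counts can be
  asserted exactly, not approximately.
- **Determinism** — all draws come from one `numpy` generator seeded per
  sample; identical configuration and seed give byte-identical files. Contig
  row order is shuffled so consumers cannot rely on generation order.

### Cohort preset

`published_cohort_preset` builds a 15-sample cohort (6 pre-treatment, 6
post-treatment, 3 control). Pre-treatment dual fractions are the six
published per-patient values (4.6–15.1%); each patient's post-treatment
fraction is its pre value plus a planted 5-percentage-point increase
(roughly the published mean increase, applied uniformly so the planted
effect is unambiguous); control fractions are the published ~12% values.
Per-sample cell counts are the published paired-cell counts scaled by 0.25
(default), keeping a full cohort near 10⁴ cells so repeated-cohort analyses
remain fast; noise rates are moderate (8% ambient, 3% low-confidence, 6%
non-productive, 3% duplicates, 25% unpaired cells, matching the published
ratio of total to paired cells in order of magnitude).

### What passing synthetic tests does and does not show

Zero-noise identifiability and exact noise bookkeeping demonstrate that the
pipeline's logic is correct: labels pass through unchanged and every rule
removes exactly what it should. They do not validate the biological
interpretation of dual-TCR calls on real data, where the generator's main
simplifications matter: real cell doublets mimic dual-TCR cells (emulated
only by the optional doublet knob; expression-based doublet removal is
upstream of this package), real chain dropout is UMI-dependent rather than
uniform, and real V/J usage and clone-size distributions are heavier-tailed
and correlated with phenotype. The planted-effect preset shows the paired
test detects a 5-point shift at these sample sizes; it says nothing about
power for smaller shifts.

## Numerical choices

- Proportion display rounding: decimal half-up, two places; invariants and
  statistics use unrounded values.
- Probability-vector validation tolerance 1e-9; frequency sum checks 1e-9.
- Tail probabilities delegate to scipy's special functions (relative
  accuracy ≈ 1e-15 in the tested range); the scipy.stats cross-check bound
  in the suite is 1e-6.
- Sorting tie-breaks: chain keys order lexicographically by (locus, V, J,
  CDR3); clonotypes by (sample, class, −size, chain keys); all output tables
  have deterministic row order.
- Problem sizes in the verification scripts — 10,000 cells × 5 replicates
  for identifiability, 10,000 null replicates per test for calibration,
  20 cohort replicates for the planted effect — were chosen as the package's
  standard verification scale: large enough that binomial noise is far from
  the asserted bounds, small enough to run routinely.

## Known limitations

- Dual-TCR calls cannot be distinguished from cell doublets using V(D)J
  data alone; upstream expression-based doublet removal is assumed.
- Chain dropout biases the single/dual split downward (a dual-α cell with
  one α dropped is counted single); the package reports what is detected.
- The "others" class conflates all higher-multiplicity configurations.
- Group labels and subset annotations are trusted inputs; no inference is
  attempted from sample names or barcodes.
- The AIRR dialect cannot carry the 10x `is_cell`/`high_confidence` flags;
  reading AIRR assumes a pre-filtered rearrangement set.
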