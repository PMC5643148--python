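# Methods

This note documents the models, defaults and numerical choices behind
`oometh`, and what the synthetic-data tests do and do not establish about
real data.

## Weighted methylation levels

Every "level" in the package is the depth-weighted level: pooled
methylated read counts over pooled total counts for the site set in
question. This is invariant under splitting/merging of the record stream
and equals the unweighted per-site mean only at uniform depth. An empty
denominator is reported as NaN — "undefined" is deliberately distinct from
a measured 0.0, and downstream operations propagate or reject it
explicitly.

Coordinates follow a single-boundary rule: per-cytosine reports store
1-based positions (Bismark convention), BED/bedGraph are 0-based
half-open, and all internal arithmetic is 0-based half-open; conversion
happens only in `io_formats`. Chromosome names are matched by exact string
equality; an explicit alias map can be supplied to the readers, because
silent renaming produces irreproducible joins. Zero-depth report lines are
retained on read — coverage filtering is an analysis decision, not an I/O
one.

Defaults with no single field convention: a 10-kb window is reported when
it has ≥ 5 covered context-matching sites (each site needs depth ≥ 1);
sparser windows are flagged excluded rather than dropped so the caller
decides. Window-level summaries report both the pooled ("global") level
and the unweighted mean of window levels, labelled as such. Between-sample
window correlation is Pearson on levels in [0, 1] (levels live on a linear
scale); Spearman is available via an argument.

## Hemimethylation calling

CG sites are palindromic, so the plus-strand C at 0-based p pairs with the
minus-strand C at p+1. Candidates are dyads with methylation ≥ 70 % on at
least one strand and read depth ≥ 10; the strand-difference test is a
Fisher exact test on [[plus_meth, plus_unmeth], [minus_meth,
minus_unmeth]] and a candidate with p < 0.05 is called hemimethylated. The
headline statistic is the hemimethylated proportion among candidates.
Choices the recipe leaves open, with our defaults:

- the test is **two-sided** (hemimethylation of either strand is
  meaningful); one could argue for one-sided variants, but the symmetric
  test is the conservative default;
- "depth ≥ 10" is applied **per strand** — the exact test is powerless on
  a near-empty strand; a combined-depth rule is available
  (`depth_rule="combined"`);
- dyads with **both** strands ≥ 70 % remain candidates; a symmetric table
  simply never reaches significance;
- **no multiple-testing correction**: the cutoff is a raw p < 0.05 by
  construction, so the proportion is an operational statistic, not a
  family-wise inference. The type-I contribution of symmetric
  fully methylated dyads is far below α at a 0.5 % read error rate
  (flipping ≥ 4 of ~20 reads on one strand is a ~4·10⁻⁶ event), which is
  why the candidate proportion tracks the injected fraction so closely.

The exact-test p-values are computed with scipy's implementation, which we
verified (test suite) agrees to < 10⁻¹⁰ with a from-scratch integer
enumeration of the hypergeometric distribution on every 2×2 table with
total depth ≤ 30. Tables repeat heavily at Poisson depths, so the caller
deduplicates tables before testing.

## Allele-specific methylation

Allele assignment happens upstream: the module accepts per-site counts
already partitioned into maternal/paternal/unassigned (or read-level
tuples), and conservation — tagged counts summing exactly to untagged
counts — is an enforced invariant. BAM-level haplotagging is out of scope.
Per-allele levels are weighted levels over assigned counts only. An ICR is
"concordant" when the expected parent's level exceeds the other's by
≥ 0.30 (a declared default; regions without assigned coverage are "no
data", never "discordant"). Genotype comparisons use a Pearson χ² without
continuity correction on the pooled read-count 2×2 table; a zero margin
yields NaN.

## Window dynamics

Windows moderately (40–80 %) or highly (≥ 80 %) methylated in the control
split into Groups 1–4 by whether the KO decrease reaches 20 **percentage
points** (a relative-decrease mode exists behind a flag). Boundary policy:
control exactly at 80 % is "high" (the bands partition everything ≥ 40 %),
a decrease exactly at 20 points is "affected" (with a 10⁻¹² float guard so
an arithmetic 0.19999…98 from 0.60 − 0.40 still counts), and windows that
gain methylation are unaffected. Windows undefined in either sample are
excluded and counted. RPKM is count / ((length/1000) · (total/10⁶));
per-group covariate contrasts use two-sided Mann-Whitney U tests, skipped
for groups with fewer than two windows. Stage gains (early = P12 − NGO,
mid = P15 − P12, late = FGO − P15) telescope to FGO − NGO exactly per
window by construction.

## Decomposition model

With control dilution factor f = L_blast^ctrl / L_FGO^ctrl, expected KO
level E = L_FGO^KO·f, total maternal loss T, de novo component D =
L_blast^ctrl − E and maintenance M = T − D, the identity D + M = T holds
exactly in both modes because M is defined as the remainder. The model
assumes a uniform maternal dilution factor and attributes all
paternal-genome loss to maintenance; these are modelling assumptions
restated here, not assertions the package tests. `printed` mode rounds f
to 2 decimals and every level to 1 decimal (percent scale, half-up via
decimal arithmetic) *before each subsequent step*, existing solely to
reproduce table-style chained arithmetic bit-exactly; `full_precision` is
the analytical default. Percent vs fraction units are auto-detected (any
input > 1.5 ⇒ percent) with an explicit override, preventing silent 100×
errors. No confidence-interval procedure is implemented: the inputs are
single pooled levels and the sample-to-sample variation is not
identifiable from them.

## Synthetic methylome generator

The generator's defaults are the study conditions the analysis targets,
not tuning knobs:

- genome: two chromosomes totalling 5 Mb → 500 10-kb windows, CG-dyad
  density 10/kb → 50,000 dyads; non-CG cytosine density 450/kb, which at a
  3.2 % per-site non-CG level puts roughly two-thirds of all 5mC at non-CG
  sites, as in fully grown oocytes;
- depth: Poisson per strand, mean 20 (the minimal standard model for
  shotgun coverage); read error (bisulfite non-conversion + sequencing)
  0.5 %, symmetric, which is what the simulated lambda spike-in
  conversion-rate estimate (≈ 99.5 %) measures;
- window classes: a lowly methylated untranscribed background (52 %), an
  early-gaining transcribed moderate class, a **late-gaining untranscribed
  moderate class that loses most of its methylation in the KO** (the
  planted structure the window-dynamics stage must recover), and high
  classes split 91:9 into KO-insensitive/sensitive — so the class table
  itself encodes moderate windows 35 % affected and high windows 9 %
  affected, and FGO global levels of 38.7 % (control), 30.8 % (maternal-KO)
  and 36.0 % (maintenance-KO) after calibration;
- calibration: class levels are rescaled once (monotone root-find against
  the realized window layout) so the expected true genome-wide CG level
  equals `global_cg_level` exactly; the observed level then sits at
  p·(1−2ε)+ε. Window-class assignment is quota-exact and spatially
  shuffled, which removes class-mixture sampling variance and makes
  "recovered within 3 binomial SE" a sharp statement;
- hemimethylation: a dyad drawn methylated (probability p/(1−h/2), which
  keeps the expected level at p) becomes hemimethylated with probability
  h on a random strand. Injection covers *every* methylated dyad — exactly
  the site-level ≥ 70 % dyads the caller selects — so the injected
  fraction is the caller's estimand; restricting injection to windows
  whose *class target* is ≥ 70 % would leave high-methylation dyads from
  moderate windows diluting the estimate by ~20 % and make the recovery
  property unattainable. Genotype defaults: 0.04 control, 12.9 % (Uhrf1
  KO), 6.8 % (Dnmt1 KO);
- preimplantation dilution: each methylated strand survives each of 5
  cleavage cycles with a fixed per-cycle probability, set from the
  aggregate survivals 14.3/38.7 ≈ 0.37 (control) and 3.1/30.8 ≈ 0.10
  (maternal-KO), so expected blastocyst level = gamete level ×
  survival^cycles; sperm is modelled as a uniform 44.9 % genome so the
  control paternal blastocyst genome lands at 16.6 %. Active paternal
  demethylation is not modelled;
- SNPs: 2/kb, placed with a 1.2× preference for transcribed windows —
  SNP-associated sites are genic-enriched, and the parental-genome average
  consequently sits slightly above the whole-genome level, the reported
  direction and rough magnitude of that bias; reads at sites within one
  read length (96 bp) of a SNP are allele-assigned, all others unassigned,
  and conservation is exact. (In a real library only reads physically
  overlapping the SNP are assignable; assigning all reads at taggable
  sites is a simplification that raises assigned depth but not bias.)

Layout (window classes, site positions, SNPs) derives from `layout_seed`,
draws from `seed`: samples with different seeds share a genome and can be
compared window by window, and a fixed (config, seed) pair is
bit-reproducible.

What the generator does **not** emulate: real sequence context (positions
are random, trinucleotides are decorative but context-consistent),
fragment-level correlation between neighbouring sites on one read,
PBAT-specific strand biases, copy-number or mapping artefacts,
transcription-coupled *non-CG* structure (non-CG sites are uniform), and
cell-to-cell heterogeneity (a dyad is a single molecule state, so
intermediate site levels arise only from hemimethylation, dilution and
error). Passing recovery tests therefore demonstrates correctness of the
analysis arithmetic and calling logic under the stated sampling model, not
robustness to alignment- or library-level artefacts.

## Problem sizes

The shipped tests and the acceptance script run at the default 5 Mb /
50k-dyad scale for parameter-recovery and planted-structure checks
(seconds per sample) and at 1 Mb for the demo pipeline; non-CG sites are
omitted from runs that measure CG-only quantities. These sizes give
3-SE bands of a few tenths of a percentage point on global levels, tight
enough to detect any systematic error in the pooling arithmetic.

## CLI and configuration

The CLI is a thin layer over the library. Run configs are YAML validated
by explicit field checks against the simulation dataclass (unknown keys
are rejected with their names; no separate schema language), every
threshold actually used is logged at INFO, and the `run` manifest records
a SHA-256 per output so determinism is checkable with `diff`. Defaults are
the canonical thresholds: 10-kb windows, hemi depth 10 / level 0.70 /
α 0.05, group bands 40–80 % and ≥ 80 % with a 20-point decrease,
concordance margin 0.3.
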