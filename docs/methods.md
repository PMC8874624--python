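# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
known limitations of the approach.

## Scope and inputs

The package starts from *annotated* mitogenomes. GenBank features of type
CDS/tRNA/rRNA are mapped to the canonical 37-gene vocabulary (13 PCGs,
22 tRNAs, 2 rRNAs) through a synonym table covering the common annotation
spellings (`ND2`, `cytochrome c oxidase subunit I`, `16S ribosomal RNA`,
`tRNA-Leu (TAA)`, ...). The duplicated Leu and Ser tRNAs are split by
anticodon — trnL1 reads CUN (anticodon UAG), trnL2 reads UUR (UAA), trnS1
reads AGN (GCU/UCU), trnS2 reads UCN (UGA) — falling back to a 1/2 name
suffix when no anticodon is annotated, and refusing to guess otherwise.
Unmappable features are skipped with a recorded warning, never silently.
Internally all coordinates are 0-based half-open; GenBank I/O converts to and
from 1-based inclusive. Missing genes are tolerated everywhere: statistics
are computed over present genes and every genome carries a completeness
report (real datasets routinely lack a gene or an rRNA in some records).

## Composition

Skews follow the Perna–Kocher convention, computed on the majority strand
(whole molecule) and on concatenated PCGs *in coding orientation*
(minority-strand genes are reverse-complemented first, since codon statistics
are meaningful only as coded). Ambiguity codes are excluded from numerators
and denominators. GC12/GC3s pool codons across genes, weighting each gene by
its codon count, with each gene's terminal codon removed; GC3s is plain
position-3 GC over all codons (the definition used in the mitogenomics
literature this package serves), not the synonymous-third-position variant
from the codon-usage literature. The neutrality plot is an ordinary least
squares regression of GC12 on GC3s across genomes; it requires ≥ 3 genomes
and non-degenerate GC3s variance, and reports slope, intercept and Pearson R.

## Codon usage

All codon statistics use NCBI translation table 5 (invertebrate
mitochondrial): 62 sense codons, stops TAA/TAG only, family structure
twelve 2-fold, six 4-fold, Leu 6-fold (UUR+CUN) and Ser 8-fold (UCN+AGN);
Met (AUR) and Trp (UGR) are 2-fold under this code.

- **RSCU**: count × family size / family total; each nonzero family sums to
  its size; zero-usage families are reported as undefined rather than 0/0.
- **Observed ENc**: Wright's statistic over the table-5 size classes
  {2: 12, 4: 6, 6: 1, 8: 1}. Per-family homozygosity uses the bias-corrected
  estimator F̂ = (nΣp̂² − 1)/(n − 1); families with n < 2 are omitted; each
  class contributes (families in class)/mean(F̂); a class with no usable
  family drops out and the sum is rescaled by 62/(sense codons represented).
  F̂ is floored at 1/s (tiny samples can otherwise go non-positive), and the
  result is clamped to [20, 62] — the bias correction can push a perfectly
  even table slightly past the theoretical maximum.
- **Expected ENc**: evaluated exactly in the printed form used by the
  comparative-mitogenomics literature, `2 + GC3s + 29/(GC3s + (1−GC3s)²)`.
  Note two deliberate literalisms: the first denominator term is *not*
  squared (Wright's original curve squares it), and the constants assume the
  standard-code family layout. It is a conventional reference curve, not a
  table-5 derivation; we reproduce the convention.
- **Correspondence analysis**: SVD of the standardized Pearson residuals of
  the row-normalized table (χ² metric). Total inertia equals the Pearson χ²
  statistic divided by the grand total; coordinates are reported in principal
  normalization; all-zero rows/columns are dropped first; a rank-0 (all rows
  proportional) table returns zero inertia with an explicit degenerate flag.
  The default codon filter for RSCU input drops stop codons and the codons
  of Met and Trp, mirroring CodonW practice; under table 5 that leaves 58
  columns (not the standard-code 59), and a switch keeps all 62.

## Saturation

Transitions are A↔G and C↔T; everything else is a transversion. Columns with
gaps or ambiguity codes are deleted pairwise (per sequence pair), matching
the default p-distance behavior of the common desktop tools. Distances are
computed per codon-position stratum and overall, and ts/tv are regressed on
total p-distance with a least-squares quadratic; the slope at the origin and
the curvature a2 support cross-stratum comparison (saturation ⇒ a2 < 0,
strongest at third positions). A constant-response input returns the exact
flat fit; a design that cannot identify a quadratic raises.

## Selection (counting-based per-site dN−dS)

The site test is a counting method in the SLAC family, with one deliberate
substitution: maximum-likelihood single ancestors are replaced by **Fitch
parsimony over the observed codon states**, averaging over all co-optimal
labelings (exhaustively enumerated when ≤ 64, otherwise sampled uniformly —
exactly, via the DP labeling counts — with a seeded generator). Branch
lengths play no role once ancestors are fixed.

Per branch with parent codon i and child codon j:

- observed counts follow all shortest single-nucleotide paths i→j; paths
  crossing a stop codon are excluded and the average renormalized (waived if
  every path crosses a stop); each step is synonymous or nonsynonymous by
  table-5 translation;
- potential sites ES/EN are the Nei–Gojobori fractions of the parent codon:
  of its 9 single-nucleotide neighbors, stop neighbors are dropped as
  inadmissible *without* rescaling, so codons with stop neighbors have
  ES+EN < 3 — consistent with excluding stop-crossing paths from the
  observed counts.

Sites with codons containing gaps/ambiguity/stops drop those taxa and
reconstruct on the induced subtree. The per-site test is a two-sided
extended binomial — the continuous beta-function extension of the binomial
CDF, valid for the fractional averaged counts — of ON out of ON+OS against
the neutral proportion EN/(EN+ES); p = 1 by convention when no substitution
was counted. A site is classed positive/negative when p ≤ α (default 0.1)
and dN−dS is respectively positive/negative. The global ratio is
(ΣON/ΣEN)/(ΣOS/ΣES), flagged undefined when no synonymous change exists.

**Validity regime.** Parsimony counting undercounts multiple hits; because
synonymous changes are the fast class under purifying selection, high
divergence inflates the dN/dS estimate (and misreconstruction can produce
apparent nonsynonymous steps even when ω ≈ 0, e.g. spurious jumps across the
split Ser family). The method is intended for the low-divergence regime of
congeneric/confamilial mitochondrial data; see the generator defaults below.

## Rearrangement typing and events

Gene orders are signed circular permutations. The canonical signature
rotates the order to start at cox1 (lexicographically smallest present gene
as fallback) and reflects the whole molecule if needed so the anchor is on
the + strand: rotation and whole-molecule reflection are annotation
artifacts, while gene-level strand flips are events. Missing genes are a
mask on the signature; a partial order joins a complete type when its
projection matches exactly one; multi-match partials stay separate, flagged
ambiguous. Type labels follow input order except the hallmark double-shuffle
signature (trnW-trnY-trnC + trnM-trnI-trnQ on the ancestral background),
which is always R1. No attempt is made to reproduce any published R2+
numbering.

The built-in reference is the ancestral insect (pancrustacean) gene order,
with strands, including the trnI-trnQ-trnM and trnW-trnC-trnY clusters; it
is user-overridable.

**Event inference** keeps a longest backbone of genes in common signed
order (best rotation × longest common subsequence, deterministic
tie-breaks), then treats each displaced, reference-contiguous,
orientation-consistent run as one event:

- *shuffle*: re-inserted adjacent to a member of its home tRNA cluster (the
  maximal tRNA run containing it in the reference) or displaced ≤ 2
  positions;
- *transposition*: re-inserted anywhere further;
- *inversion*: strand-flipped in place; *inverse transposition*:
  strand-flipped and remote.

The "home cluster" criterion is one formalization of the informal
shuffle/transposition distinction in the descriptive literature; the
distance-only alternative misclassifies remote moves near long tRNA runs.
Replaying the inferred events onto the reference must reproduce the observed
order exactly (checked on every call); the event count is an upper bound on
the true minimum (no claim of minimal sorting, which is hard in general).
Breakpoint distance counts signed circular adjacencies of one order absent
from the other, restricted to shared genes.

**Tree mapping** reports, for each type and each named derived feature
(both cluster shuffles and the trnL2-to-trnI-trnQ-trnM relocation are
built in), the smallest clade containing all carriers and whether it is a
clean synapomorphy (no non-carrier tips inside; offenders listed).

## Synthetic data

The generator reproduces the statistical regime the analyses assume, not
biological sequence content:

- **Genomes**: ~15.7 kb, all 37 genes at realistic lengths plus a 1 kb
  control region and 0–3 nt spacers; majority-strand composition targets
  A+T = 0.82 and GC skew = −0.2 (AT skew 0) applied everywhere — genes on
  the minority strand are generated against the complemented target so the
  assembled majority strand still hits it; PCGs are stop-free random codon
  strings ending in TAA. No real homology, no control-region structure, no
  within-genome rate heterogeneity: parsing, composition and gene-order
  analyses are fully exercised, but nothing downstream should be read as
  evidence about real sequence alignments.
- **Gene orders**: planted types are the ancestral order, the R1 double
  shuffle, and further types stacking 1–4 random tRNA events (adjacent
  swaps, moves, in-place inversions), redrawn until signatures are pairwise
  distinct; every type gets ≥ 1 of the 104 genomes.
- **Alignments**: independent codon sites on a random pairing topology with
  exponential branch lengths, evolved under a Muse–Gaut-style rate matrix
  (single-nucleotide exchanges × target-base frequency × κ for transitions
  × ω for nonsynonymous; stops excluded), root codons from the mutation-bias
  stationary composition, matrix exponentials cached per branch length.
  Defaults: ω = 0.13 (the strong-purifying regime of ichneumonid
  mitochondrial PCGs), κ = 2, AT bias 0.82, 16 taxa × 2000 codons for the
  recovery experiments, and **branch_mean = 0.03** expected substitutions
  per codon per branch. The branch length keeps pairwise divergence in the
  low-divergence regime the counting estimator assumes: at ~3× longer
  branches parsimony undercounting of synonymous multiple hits inflates the
  global estimate by ~0.03–0.04. Passing the recovery test therefore shows
  correctness of the counting machinery in its intended regime, not
  robustness to saturation.

All randomness flows from one integer seed through numpy Generators; fixed
seed ⇒ byte-identical files.

## Pipeline

One declarative TOML config drives all stages; absent inputs skip their
stages with a logged notice, a failing stage does not stop independent ones,
and outputs are TSVs plus a manifest of SHA-256 checksums (identical inputs
⇒ identical bytes). Defaults surface the analysis parameters: α = 0.1,
CodonW-style codon filter, quadratic saturation fits, all four strata.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code path
with tight tolerances: exhaustive-oracle comparisons on ≤ 4-taxon,
≤ 10-codon instances; ω-recovery on ten seeds of 16 × 2000 codons;
rearrangement recovery on 104 genomes / 38 planted types and 200
single-event replicates; 100 random tables for the CA χ² identity. The
acceptance script regenerates all of these from one seed.

## Known limitations

- Gene-order event calls are a greedy upper bound; complex nested events may
  be over-segmented, and the shuffle/transposition boundary is a convention.
- The site test's size is approximate (counting + doubling convention);
  under neutrality simulations the significant fraction stays well under
  nominal-plus-slack but is not exactly α.
- The expected-ENc curve and the CA codon filter are standard-code
  conventions applied, knowingly, under table 5.
- Exact reproduction of published values for any real dataset additionally
  requires that dataset's accessions, alignment and tree.
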