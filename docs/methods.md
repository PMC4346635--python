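# Methods

`chicflow` implements an analysis pipeline for capture Hi-C (cHi-C): Hi-C with
hybridization capture of selected target regions, which raises coverage of
contacts involving those regions by two orders of magnitude and thereby the
effective resolution at which interactions can be called.  This note records
the models, the parameters that matter, the numerical choices, and what the
bundled simulator does and does not emulate.

## Coordinate conventions

All genomic coordinates are 0-based, half-open.  Bins of a fixed resolution
(9 kb genome-wide; 3 kb for close-cis analysis) tile each chromosome, the last
bin truncated.  The contact matrix stores the upper triangle (i ≤ j) of the
symmetric bin-pair count matrix M_ij.

## Restriction geometry and ditag filtering

The experiment's unit of observation is the *ditag*: two single-end read
alignments sharing a read id, each end mapping near a restriction-site
junction.  HindIII (`A^AGCTT`, cut offset +1) is the default enzyme; sites
average ~3 kb apart, which bounds the intrinsic resolution.

Filters, in order:

1. **Mapping quality** — both ends must exceed MAPQ 30 (strict inequality);
   read ids with a single aligned end are dropped as singletons.
2. **PCR duplicates** — ditags identical on (chrom, pos, strand) of both ends
   after canonical end ordering collapse to their first occurrence.
3. **Artifact geometry** — with ends canonically ordered (end 1 upstream),
   inward = (+,−) and outward = (−,+):

   | geometry                         | class          |
   |----------------------------------|----------------|
   | either end > 800 bp from any cut | `no_site`      |
   | same fragment, inward            | `non_digested` |
   | same fragment, outward           | `self_ligation`|
   | adjacent fragments, outward      | `circularized` |
   | anything else                    | `valid`        |

   The 800 bp default reflects sonication fragment sizes peaking near 500 bp:
   a read farther than that from every cut site cannot flank a real ligation
   junction.  The distance rule dominates the orientation rules.  Inward pairs
   on adjacent fragments (possible re-ligation) are retained as valid; this is
   a deliberate, documented choice and a knob for sensitivity analysis.

Filter accounting is exact: category counts are disjoint and sum to the input
pair count.

## Bins, capture classes and the valid-bin filter

A bin is *enriched* (E) if it overlaps a capture bait interval by at least
1 bp, otherwise *non-enriched* (N).  Bin pairs fall in classes E–E, E–N, N–N;
only E–E and E–N pairs are eligible for interaction calling, because capture
leaves N–N coverage too shallow to test.  A bin is *valid* if it contains at
least one restriction cut site and its length-weighted mean mapability is
strictly greater than 0.5 (with no mapability track supplied, every bin
scores 1.0 and the filter passes vacuously — appropriate for synthetic
genomes).  Invalid bins are excluded from all downstream analysis.

## Iterative bias correction

Per-bin visibility differences (fragment-length structure, GC, mapability,
and — at resolutions near the mean fragment length — the unequal distribution
of restriction sites over bins) multiply contact counts roughly as b_i·b_j.
The correction estimates per-bin weights from *trans* contacts, which sample
visibility without the strong distance structure of cis data:

  w_i  = total trans contact count of bin i
  N_i  = number of populated trans entries in row i
  W, A = totals of w_i and N_i over retained bins
  ŵ_i  = (w_i / N_i) · (A / W)

Each iteration divides M_ij by (ŵ_i·ŵ_j)^ω and recomputes the weights until
max |ŵ_i − 1| ≤ tol (default 1e-3, max 100 iterations; non-convergence is
reported, never silent).  The update is damped (ω = 0.5 by default): on
capture data the weight structure is bipartite-like (bait rows versus the
rest), full steps excite a slowly decaying alternation between the classes,
and the half step suppresses it without moving the fixed point.  Bins whose
initial weight lies more than three standard deviations below the mean are
discarded before iterating; with a capture design the weight distribution is
a two-scale, strongly right-skewed mixture on which a linear three-s.d. rule
never triggers, so the rule is applied to log-weights within each capture
class — same intent (drop the low-visibility bins that destabilize the
recursion and whose correction amplifies counting noise), spread measured
where it is meaningful.  Zero-weight bins are always dropped when trans
information exists.  After convergence the matrix is rescaled to its input
mass.  The correction
identifies bias up to one overall factor per chromosome (weights are
trans-derived), which is immaterial because every downstream fit is
per-region.

Two implementation decisions matter in practice:

* **Capture-class restriction.**  With a capture design present, only E–E and
  E–N entries enter the weight sums.  The N–N trans mass is so sparse (counts
  of 0 or 1 per pair) that its populated-entry count tracks its contact count
  one-to-one, which drives every per-populated-entry rate w_i/N_i to the
  global rate and blinds the recursion to real bias; restricting the weights
  to the capture classes — the entries the analysis actually uses — restores
  identifiability.  Without baits (plain Hi-C mode) all trans entries are
  used.
* **No windowing.**  The 10 Mb moving window used for memory reasons at
  genome scale is algebraically irrelevant here: weights are per-bin and
  global, so dividing M_ij by ŵ_i·ŵ_j windowed or globally is identical.
  Window tiling is still provided for heatmap export.

## Distance normalization

Cis contact frequency decays with genomic separation as a two-regime power
law: exponent ≈ −0.52 over 9 kb < d < 0.5 Mb and ≈ −0.97 over
0.5 Mb ≤ d ≤ 7 Mb.  The expected-contacts template is built by

1. computing, for every bin separation k, total contact mass divided by the
   number of valid bin pairs at that separation (zero-count pairs count in
   the denominator);
2. trimming one boundary separation bin per side (partially covered by the
   observable range, they would tilt the slopes);
3. aggregating onto ~80 log-spaced distance bins, pair-weighted;
4. smoothing log f against log d with a Gaussian-kernel *local linear*
   regression (bandwidth 0.1 decades).  Local linear, not a kernel mean: a
   pure power law is a straight line in log-log space and must remain one at
   the support boundaries, where a Nadaraya–Watson mean flattens and biases
   the fitted exponents;
5. enforcing monotone non-increase.

Regime slopes are fitted by least squares on the smoothed profile over the
two ranges.  Each cis entry is then divided by the template value at its
bin-midpoint separation (log-log interpolation); trans entries are untouched.
An optional coverage attenuation γ = clip((c/c_ref)^λ, ε, 1], with c the
interactor-side capture coverage and c_ref the median over enriched bins,
applies the correction as f^(−γ): low-coverage interactors are penalized
less.  The attenuation is off by default (γ = 1, pure Hi-C mode); its
functional form is this package's own, chosen to satisfy the qualitative
contract (monotone, bounded, full correction at reference coverage).

## Significance: zero-inflated Weibull null

Normalized strengths of testable pairs (E–E and E–N, both bins valid,
separated by more than 10 kb in cis — bin distance ≥ 2 at 9 kb — or trans)
are modelled as a zero-inflated Weibull: point mass π at zero, Weibull(κ, λ)
for positive strengths.  π is the observed zero fraction over the *universe*
of testable pairs (zeros included by construction).  κ and λ maximize the
Weibull likelihood over nonzero strengths at or below their 95th percentile,
with the likelihood renormalized for the right truncation — the truncation
keeps genuine interactions out of the null, the renormalization keeps the
estimator consistent.  Optimization is Nelder–Mead on (log κ, log λ) from a
coefficient-of-variation initialization; fits require ≥ 200 nonzero values,
intervals below that fall back to the pooled fit of their context.
Degenerate inputs raise.

P(x) = 1 at x = 0, else (1−π)·exp(−(x/λ)^κ).  Test-region (E–E) strengths are
pooled into one fit; cis and trans pairs are fitted per interactor 10 Mb
window.  Benjamini–Hochberg q-values (per library, over the whole universe)
define significance at q < 0.05; with several libraries a contact is
*shared-significant* when q < 0.05 in every library.  BH is used for the FDR
step as the parameter-free default.

### Overlap of call sets across libraries

For k contacts shared by three libraries with per-library call counts n_i
from testable universes of sizes N_i (nested S1 ⊆ S2 ⊆ S3), each element of
the smallest universe is in all three call sets with probability
p = Π n_i/N_i under independence, so the overlap K ~ Binomial(N1, p).
P(K ≥ k) is evaluated with `binom.logsf` and reported as a "< 1e-16"-style
bound beyond double precision.  Inputs may be given in any order; pairs are
sorted so S1 is the smallest universe.  An exact without-replacement
evaluation (hypergeometric chain: |s1∩s2| ~ HG(N2, n1, n2), then
K | · ~ HG(N3, ·, n3)) is provided as an oracle; the binomial model
approximates it closely for large sparse universes but is not identical for
tiny ones.

## Directionality index and domains

For each bin, A and B are the contact sums to bins strictly upstream and
downstream within a 495 kb flanking window (truncated at chromosome edges);

  D = |A − B| · (B − A) / (A + B),   D = 0 when A + B = 0.

|D| = (A−B)²/(A+B) is asymptotically χ²(1 d.f.) under the symmetric null
A ~ Binomial(A+B, ½).  DIX is computed on bias-corrected but *not*
distance-normalized counts — distance normalization would whiten exactly the
directional signal the statistic measures.

Domain segmentation decodes a 3-state HMM (downstream-biased / none /
upstream-biased) over the variance-stabilized signal sign(D)·√|D|: Gaussian
emissions with means (+s, 0, −s), s the signal's standard deviation, shared
variance s², sticky transitions (0.9 self-transition), Viterbi decoding
(optionally Baum–Welch-refined via hmmlearn).  A domain runs from the start
of a downstream-biased run to the end of the next upstream-biased run, with
newer downstream runs superseding older ones — this keeps the truncated-
window artifact at chromosome starts from swallowing the first real boundary
— and must span at least 3 bins.  A flat track yields no domains.

## Downstream statistics

* **Enrichment factor** — on-target read fraction (either end inside a target
  interval) of the captured library divided by that of an uncaptured
  reference, both subsampled (seeded) to equal raw size first; duplicates do
  not scale linearly with library size, so size-matching is required for the
  ratio to mean anything.  A zero on-target reference yields an infinity
  sentinel with a warning.  A per-bin mean on/off-target count ratio is
  reported alongside.
* **Association overlap** — two-sided Fisher exact test on the 2×2 table of
  (significant vs not) × (overlapping a strong association signal vs not),
  where a bin overlaps a strong signal if it contains a variant with P within
  one order of magnitude of its region's minimum.
* **Regulatory-element overlap** — Monte Carlo: the observed proportion of
  significant bins overlapping an element class versus the proportions in
  seeded random same-size draws (without replacement within a draw) from the
  valid-bin universe; P = m_c/N with "< 1/N" reported when no draw reaches
  the observed proportion.
* **TF sharing** — per interacting pair, the number of factors with a peak in
  both bins; control pairs permute interactors across calls, rejecting pairs
  whose bins share a test region; two-sided Mann–Whitney U compares real and
  control counts.  All-zero counts short-circuit to P = 1 with a degenerate
  flag.
* **Chromatin-state regrouping** — segmentation labels map to a simplified
  scheme (promoter / enhancer / transcribed / other); adjacent same-class
  intervals merge; unmapped labels raise, listing the offenders.

## The simulator

`SimulationConfig` defines a complete synthetic experiment; every pipeline
stage has a closed-loop test against its ground truth.  Defaults: two 20 Mb
chromosomes, 3 kb mean site spacing, library of 5×10⁵ ditags, capture fold
130, decay exponents −0.52/−0.97 with the break at 0.5 Mb, per-bin log-normal
bias σ = 0.3, artifact fractions 2/2/1/2% plus 5% duplicates.  The generative
model:

* **Genome** — random sequence with `AAGCTT` planted at exponential gaps and
  scrubbed elsewhere, so a digest recovers exactly the planted sites.
* **Cis background** — per locus pair, contact probability ∝ d^α (two
  regimes); ends snapped to within ±300 bp of a restriction site, as real
  ligation junctions are.  The snapping reproduces a genuine bias of real
  data: bins differ in restriction-site catchment, giving per-bin visibility
  variation on top of the configured log-normal bias.
* **Per-pair dispersion** — contact rates between fixed locus pairs vary far
  beyond Poisson in real data.  Quenched mean-1 multipliers are drawn per bin
  pair from a Weibull with shape 2.5 (CV ≈ 0.43), clipped at the 1−1e-4
  quantile, deterministic in (seed, pair) via splitmix64 hashing.  The
  Weibull family is chosen deliberately: the significance model fits a
  Weibull null, and that model family is only appropriate for data whose
  strength distribution is Weibull-like — a heavier family (e.g. log-normal)
  has a tail no fitted Weibull can cover, and a much lighter one would make
  the planted 5-fold loops trivially separable.  At shape 2.5 a 5-fold
  signal sits roughly four null standard deviations above the mean, the
  operating regime a capture design is built to reach.
* **Capture** — the configured fold F is the *measured* enrichment factor;
  the library is composed with on-target share q = f·F (f estimated from the
  uncaptured candidate pool; f·F ≤ 1 required), with a bait-anchored
  conditional generator supplying the on-target mass that unconditioned
  sampling cannot.  "On-target" means an end inside a bait interval — the
  capture chemistry's criterion, not the analysis binning.
* **Loops** — anchors receive Poisson extra mass of (fold−1) × the local
  background expectation, estimated from same-class pairs at similar
  separation and scaled by the interactor bin's relative cis coverage, so the
  planted mass carries the same per-bin visibility as its background and the
  effective planted fold is homogeneous across anchors.
* **Domains** — within-domain cis candidates are up-weighted by the
  configured ratio.
* **Artifacts** — each class is emitted with exactly the fragment geometry
  that triggers its filter rule; duplicates are literal copies of emitted
  ditags.

What the simulator does **not** emulate: sequence-level reads (no FASTQ, no
alignment or mapping ambiguity — MAPQ is constant 60), GC- or
fragment-length-dependent bias beyond the per-bin factor, inter-chromosomal
structure (trans background is uniform), cell-to-cell heterogeneity, and
copy-number variation of cancer genomes.  Closed-loop test results therefore
demonstrate internal consistency of the pipeline under its own model
assumptions, not performance on real libraries.

## Problem sizes

Tests run the simulator at desk scale: most fixtures use 2 × 6–20 Mb
chromosomes and 5×10⁴–5×10⁵ ditags.  The full interaction-calling closed loop
reproduces the study design end to end: three libraries of 1.5×10⁶ ditags
with bait regions on both chromosomes, per-library structural noise fields
(cell lines differ in line-specific chromatin structure — the very reason the
analysis requires q < 0.05 in every library), 20 loops planted at 5-fold, and
shared-significant calls evaluated against the planted set.  Library sizes
are chosen so captured rows reach the per-pair depth (tens of contacts per
testable pair) at which a parametric tail fit is meaningful — the regime the
real capture design targets.  Distance-decay exponent recovery uses 10⁶
contacts on a 20 Mb chromosome.

## Known limitations

* The trans-derived weights leave one free scale factor per chromosome; only
  per-region-normalized quantities are comparable across chromosomes.
* The ZIW tail is an extrapolation from the bulk; on data whose strengths are
  not Weibull-like beyond the 95th percentile the calibration of extreme
  q-values degrades (sparse matrices with per-pair counts in the low single
  digits are the canonical failure mode).
* The combinatorial overlap test assumes independent uniform sampling; the
  binomial model slightly mis-states the exact without-replacement law for
  small universes (an exact oracle is provided).
* The domain caller is a single-scale segmentation; nested domains are out of
  scope.
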