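# Methods

This note documents the models, parameter choices, and known limitations of
`embryoatac`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Biological setting

Before the midblastula transition (MBT), *Drosophila* embryos cycle through
rapid, synchronous S/M nuclear cycles (NC11–NC13; haploids add NC14). Two
timers govern MBT events: elapsed developmental time and the
nucleo-cytoplasmic (N:C) ratio — DNA content per cytoplasm. Haploid embryos
carry half the DNA, so they reach any N:C ratio exactly one cycle later
than diploids; comparing the two genotypes at matched time versus matched
ratio separates the two timers. The package analyzes when accessible
chromatin regions are first established, whether they persist through
mitotic metaphase, which timer controls them, and how promoter nucleosome
architecture is disrupted and recovered around each round of DNA
replication.

## Fragment model and the open/nucleosomal split

Fragments are 0-based half-open genomic intervals; the Tn5 correction
widens each interval outward (start − 4, end + 5), following the original
pipeline's interval-level recipe rather than the common inward +4/−5
convention applied to read starts (`convention="centered"` selects the
alternative). Lengths used by the ≤ 98 bp split are post-correction.

Insert lengths are modeled as a mixture of one exponential (nucleosome-free
inserts) and *k* Gaussians (mono-, di-nucleosome protection), fit by EM:
exponential rate initialized from lengths < 100 bp, Gaussian means at
200·k bp, 500 iterations maximum, relative log-likelihood tolerance 1e-8.
The crossover — the smallest length where the weighted first Gaussian
density exceeds the weighted exponential — is solved analytically from the
log-density quadratic; a 1 bp grid scan serves as the independent check in
tests. Non-convergence raises an error that carries the last fit (a pure
exponential sample legitimately drifts along a flat likelihood ridge for
the unused Gaussian).

## Coverage normalization

Open-fragment coverage is binned (10 bp), scaled to counts-per-million of
the full unsplit library (so stage-dependent open/nucleosomal proportions
do not inflate open coverage), and standardized genome-wide against
background regions: peaks widened symmetrically to 20 kb, merged,
subtracted from the genome; positions sampled uniformly from the
complement with widths resampled from the peak-width distribution
(truncated at gap edges); regions with zero coverage discarded without
replacement. Because background coverage is approximately log-normal,
μ/σ are computed on log per-region mean coverage with pseudocount
ε = (smallest positive bin value)/2, and the genome-wide transform is
z = (log(x + ε) − μ)/σ (a raw-space variant is selectable). The transform
is exactly invertible given (μ, σ, ε).

At desk-scale library sizes (tens of thousands of fragments over a few Mb)
a substantial minority of background regions have zero coverage and are
discarded; with genome-scale libraries the discarded share is small. This
affects only the retained-region count, not the transform's semantics.

## Peak calling

The caller is a documented stand-in occupying the slot of a zero-inflated
mixed-regression peak caller in the original design, keeping its
operational parameters: 300 bp windows at 50 bp steps, FDR 0.05, zero merge
gap, 75 kb local-background window, score retention ≥ 0.8, summit
refinement. Windows are scored against a local negative-binomial background
whose mean/variance come from method-of-moments over the surrounding 75 kb
of window counts, floored at Poisson; windows far in the upper Poisson tail
of the chromosome's median rate are masked from the moment estimates so
enrichment does not inflate its own background. Per-window p-values are
Benjamini–Hochberg corrected genome-wide; significant windows merge, and
merged regions are split at insertion-density valleys (runs of > 30 bp of
10 bp bins without fragment midpoints), trimmed to their occupied span,
with the summit at the lightly smoothed density maximum (leftmost tie).
Peak score is 1 − q of the best constituent window; this is an operational
confidence, not a posterior probability, and the ≥ 0.8 retention is kept as
the filter without claiming statistical equivalence to the original tool's
posterior.

Window-level FDR control does not bound peak-level FDR: with deep pooled
libraries, isolated false windows each become a small peak while true
windows aggregate into few peaks. Downstream presence calls are
overlap-based and robust to this; the union-vs-per-cycle "absent" class
absorbs most such slivers.

## Feature, timing, and dependence classification

Categories follow strict precedence — promoter (any overlap with
TSS ± 50 bp, strand-independent), then insulator (≥ 2 distinct insulator
proteins), then enhancer (validated enhancer or ≥ 2 evidence marks), else
other — with raw per-annotation overlap flags retained alongside, since
exclusive precedence counts and per-annotation totals answer different
questions. Timing is first-present-cycle over per-cycle pooled calls
(any ≥ 1 bp overlap; configurable). Dependence scoring considers only
dynamic peaks (new at NC12/NC13) present in the haploid union; presence at
matched time ⇒ time-dependent (a time match takes precedence over a ratio
match, since presence at the earlier developmental time already
demonstrates N:C independence); absent at matched time but present at
matched ratio ⇒ N:C-ratio-dependent; otherwise unscored with the reason
recorded.

Fisher exact tests use the sample odds ratio ad/bc (∞ and 0/0 handled
symbolically) and the exact two-sided hypergeometric tail; the test suite
verifies agreement with exhaustive enumeration to 1e-12 on all tables with
total ≤ 30. Permutation tests preserve group sizes and use the add-one
estimator p = (1 + #{perm ≥ obs})/(n_perm + 1), one-tailed, with
median-difference default (mean-difference selectable); bootstrap CIs for
median differences use 10⁴ percentile resamples.

## Nucleosome architecture

Dyads are local maxima of Gaussian-smoothed (σ = 20 bp) midpoint density of
fragments with lengths 117–250 bp (well-defined mononucleosome midpoints),
minimum separation 120 bp, with maxima below 20% of the region's density
maximum suppressed; occupancy is the smoothed density at the dyad. This is
a stand-in for a fragmentation-model nucleosome caller; external dyad
tables are accepted interchangeably. Dyads widen to [dyad − 73, dyad + 74)
— 147 bp with left-biased rounding. The NFR vantage is 25 bp upstream of
the TSS in transcription orientation (strand-aware; using the TSS itself
would misidentify a TSS-occluding +1 nucleosome as the −1), and
NFR size = |+1 dyad − −1 dyad| − 147, the inner-edge gap of the modeled
nucleosomes. The size can be negative when dyads sit closer than one wrap;
mean-normalized group dynamics are invariant to the constant 147 offset.
Promoters missing either flanking dyad are omitted with the reason
recorded.

Occupancy heatmaps cover TSS ± 400 bp, oriented with transcription
left→right, rows ordered by time-averaged −1 position; column averages are
reported raw, log10, and flank-normalized (mean of the two flanking 200 bp
margins = 1). Recovery latency interpolates each locus' per-timepoint
maximum standardized open coverage with a natural cubic spline on a
0.1-minute grid and reports the earliest time the interpolant reaches the
preceding metaphase's value; loci that never recover are censored at cycle
end and retained with a flag; the per-cycle median of raw (grid) latencies
and per-cycle log2 fold changes (last/first timepoint) are also reported.

## Synthetic study conditions

The generator's defaults are the study conditions the tests run under:

- **Genome**: two chromosomes of 1 Mb, 200 non-overlapping truth peaks
  (300–800 bp, ≥ 3 kb apart), timing proportions 31/39/30%
  (NC11/NC12/NC13), N:C-dependent share 61% of peaks (the study's scored
  split), metaphase persistence probability 0.75, latent feature mix
  30/15/35/20% (promoter/insulator/enhancer/other) with annotations wired
  to the latent category (promoter peaks carry a TSS; insulator peaks ≥ 2
  protein tracks, plus GAF when N:C-dependent; enhancer peaks a validated
  enhancer — first active early with probability 0.452 — or ≥ 2 marks,
  Zelda for time-dependent ones).
- **Libraries**: 13 timepoints at 3-minute spacing per genotype (NC11:3,
  NC12:4, NC13:6; haploids shifted one cycle), 40,000–50,000 fragments per
  sample. Insert-length mixture: exponential scale 23 bp shifted by a
  10 bp minimum insert, nucleosomal Gaussians (170, 360) ± (50, 60) bp
  truncated at 100 bp, weights 0.45/0.45/0.10 — chosen once so the *fitted*
  open/nucleosomal crossover lands in the 100–110 bp range, just above the
  conventional 98 bp cutoff (the crossover value itself is not asserted
  anywhere). 75% of open fragments land in truth peaks whose onset has
  passed (uniform within the peak), the rest uniform; 60% of nucleosomal
  fragments are TSS-phased at −180/+135 bp with 20 bp per-fragment jitter.
- **Early-S disruption**: within 3 minutes of anaphase, each promoter's
  −1/+1 dyads take a shared random displacement (sd 30/20/5 bp at
  NC11/12/13 — whole-nucleosome repositioning after fork passage, which is
  what moves *called* dyads rather than merely blurring them) and open
  fragment yield drops by 50/35/10%.
- **Metaphase**: only persistence-flagged peaks retain open fragments.
- **Movies**: nuclei as uniform disks plus Gaussian foci whose summed
  intensity is the planted focal fraction; the active-focus count scales
  with the fraction (more replication factories at S-phase peak); shot
  noise before a 1 px PSF blur (so noise is spatially correlated, as in
  projected confocal data), per-nucleus totals renormalized exactly when
  conservation is enabled. The texture statistic discriminates well for
  focal fractions up to ~0.5, the default trajectory's peak; with
  per-nucleus min–max quantization, saturation flattens the response above
  that.

What the generator does **not** emulate: sequence composition and
mappability structure, GC or Tn5 sequence bias, PCR duplicates,
mitochondrial carry-over, copy-number variation, replicate-level batch
variation, partial synchrony between nuclei, and continuous (rather than
stepwise) accessibility onset. Passing tests therefore demonstrate that the
*analysis machinery* recovers planted structure under clean conditions;
they do not certify performance on real libraries with these confounders.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; BED writers follow the BED
  standard.
- Identical (config, seed) reproduces bitwise-identical outputs; per-sample
  seeds in a series are spawned from the series seed.
- Desk-scale problem sizes (2 Mb genome, 200 truth peaks, ~40k-fragment
  samples, 200 synthetic promoters for dyad recovery, 1000 null datasets at
  1000 permutations) were chosen so the full suite and the acceptance
  script each complete in a few minutes on one CPU; recoveries at these
  sizes are comfortably inside their tolerances.
- The per-peak accessibility statistic behind median traces is the maximum
  of standardized coverage within the region (mean selectable), matching
  the NFR accessibility definition.
- "Homogeneity" is the standard inverse-difference co-occurrence statistic
  Σ P(i,j)/(1 + |i−j|); quantization is per-nucleus min–max into six equal
  bins (global-range selectable); "radial sets of eight pixels at 200 nm"
  is read as eight angular offsets at a fixed pixel distance of
  round(200 nm / pixel size).
- Background-region statistics use the mean of a region's bins (sum
  selectable); discarded zero-coverage regions are not replaced.
- Degenerate inputs: empty fragment sets propagate as empty results with
  warnings; σ_bg = 0 raises a degenerate-background error; constant-
  intensity nuclei score heterogeneity 0; nuclei too small to host a pixel
  pair at the offset distance are flagged NaN.

## Known limitations

- Peak-level FDR exceeds window-level FDR on deeply pooled libraries (see
  above); presence-based downstream calls absorb this by design.
- The EM length-mixture model is intentionally simpler than the generator's
  law (shift and truncation are not modeled), so fitted parameters carry a
  small systematic bias; parameter-recovery tests therefore simulate from
  the model family itself.
- The dyad caller resolves nucleosomes no closer than 120 bp and inherits
  midpoint-density bias at region edges.
- Recovery latency uses an unconstrained natural cubic spline; with very
  sparse timepoints the interpolant can overshoot between samples (raw-grid
  latencies are reported alongside for this reason).
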