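# embryoatac

Time-resolved single-embryo ATAC-seq analysis of how chromatin accessibility
is first established in the early *Drosophila* embryo — across the rapid
syncytial nuclear cycles (NC11–NC13) that precede the midblastula transition
(MBT) and large-scale zygotic genome activation.

The package is a library with a ground-truth synthetic-data generator, so
every stage of the analysis is testable end to end without external data.
It is aimed at epigenomics researchers who want to reproduce, probe, or
extend this style of staged-embryo accessibility analysis.

## What it computes

Given fragment-level ATAC data (BED3+ intervals with per-sample stage
metadata), the pipeline:

1. **Fragment pre-processing** (`fragments`, `mixture`) — reads fragment
   files restricted to the canonical chromosome set, applies the Tn5
   insertion-site correction (start − 4, end + 5, so lengths grow by 9 bp),
   and splits libraries at ≤ 98 bp into "open" (nucleosome-free) and
   nucleosomal fractions. The cutoff is motivated by a maximum-likelihood
   fit of insert lengths to a mixed exponential/Gaussian model
   f(x) = w₀·λe^(−λx) + Σₖ wₖ·N(x; μₖ, σₖ); the crossover where the first
   nucleosomal component overtakes the exponential falls near 100 bp.
2. **Coverage and normalization** (`coverage`) — open-fragment counts in
   10 bp bins, scaled to counts-per-million of the *full* (unsplit) library,
   then standardized genome-wide as z = (log(x + ε) − μ_bg)/σ_bg against
   25,000 randomly placed background regions sampled from the complement of
   peaks widened to 20 kb.
3. **Peak calling** (`peaks`) — pooled open fragments scored in 300 bp
   windows (50 bp step) against a local negative-binomial background
   (method-of-moments over 75 kb), Benjamini–Hochberg FDR 0.05, merged and
   refined on 10 bp insertion density; peaks with confidence score < 0.8
   are dropped.
4. **Feature and timing classification** (`annotation`) — promoter
   (TSS ± 50 bp) > insulator (≥ 2 of CTCF, GAF, BEAF32, CP190, Mod(Mdg4),
   Su(Hw)) > enhancer (validated enhancer or ≥ 2 of CBP, H3K4me1, H3K27ac,
   Zelda) > other; per-cycle timing classes (open by NC11 / new at NC12 /
   new at NC13); metaphase maintenance fractions; Fisher exact enrichment
   (odds ratio ad/bc, exact two-sided p).
5. **N:C-ratio vs time dependence** (`ncratio`) — haploid embryos reach a
   given nucleo-cytoplasmic ratio one cycle later than diploids
   (diploid NC11/12/13 ↔ haploid NC12/13/14 at ratios 0.25/0.5/1.0).
   Dynamic diploid peaks present in haploids at matched time are
   time-dependent; those present only at the matched ratio are
   N:C-ratio-dependent. Median-accessibility traces and one-tailed
   permutation tests (p = (1 + #{perm ≥ obs})/(n_perm + 1)) quantify the
   group separation.
6. **Nucleosome architecture** (`nucleosome`) — dyads called as local maxima
   of Gaussian-smoothed nucleosomal-fragment midpoint density (σ = 20 bp,
   minimum separation 120 bp), modeled into 147 bp nucleosomes; promoter
   NFR measured between the −1/+1 dyads flanking the TSS − 25 bp vantage
   (NFR size = dyad gap − 147); occupancy heatmaps, mean-normalized NFR-size
   dynamics with bootstrap CIs, and spline-interpolated recovery latency of
   post-replication accessibility.
7. **Replication-focus imaging** (`imaging`) — per-nucleus GLCM texture on
   fluorescence movies: six gray levels, eight radial offsets at ~200 nm,
   heterogeneity = 1 − Σ P(i,j)/(1 + |i−j|), scaled by relative mean
   intensity to estimate S-phase replication activity.

The `synthetic` module generates annotated toy genomes, fragment
timecourses for both genotypes (with planted timing classes, dependence
labels, metaphase persistence, TSS-phased nucleosomes at −180/+135 bp, and
early-S disruption), and focal-fluorescence movies — all bitwise
reproducible from a single seed.

The peak caller and the dyad caller are deliberately lightweight stand-ins
occupying the slots of heavier external tools (a zero-inflated-regression
peak caller and a fragmentation-model nucleosome caller) in the original
design: they consume and produce the same record shapes, and externally
produced peak BEDs or dyad tables are accepted interchangeably.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/03_haploid_nc_ratio.py
cycle pairing at matched N:C ratio: [(11, 12), (12, 13), (13, 14)]

293 dynamic diploid peaks scored:
{'unscored': 120, 'nc_dependent': 115, 'time_dependent': 58}
present in haploids at matched time: 19.8%
present in haploids at matched N:C ratio: 58.0%
-> most dynamic peaks are absent at matched developmental time but
   present at the matched ratio: their opening follows the N:C timer.
```

Dynamic peaks (those gaining accessibility at NC12/NC13) are overwhelmingly
absent from haploids at the same developmental time yet present one cycle
later at the matching N:C ratio — the signature of N:C-ratio-timed
chromatin opening. Similarly:

```bash
$ python examples/05_nucleosome_nfr.py
dyads called: 114  modeled nucleosomes: 114 (147 bp each)
promoters with both -1 and +1: 57 of 57
mean +1 offset: 135 bp downstream   mean -1 offset: 180 bp upstream
mean NFR size: 168 bp (dyad gap minus the 147 bp wrap)
...
```

recovering the canonical fly promoter architecture (−1 nucleosome 180 bp
upstream, +1 nucleosome 135 bp downstream of the TSS, NFR ≈ 168 bp).

A thin CLI mirrors the main steps for shell use:

```bash
embryoatac simulate --seed 1 --out-dir sim/
embryoatac split sim/fragments_diploid_NC13_6min.bed --no-tn5-adjust --out-prefix nc13
embryoatac callpeaks nc13.open.bed --chrom-sizes sim/chrom.sizes --out peaks.bed
embryoatac classify peaks.bed --annotations sim/ --out classified.tsv
```

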