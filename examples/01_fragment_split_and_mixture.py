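"""Split a fragment library by insert length and fit the length mixture.

ATAC insert lengths are bimodal: short fragments from nucleosome-free DNA
(~exponential) and longer nucleosome-protected fragments (~Gaussian around
the ~180 bp mononucleosome span). The fitted crossover between the two
weighted densities motivates the conventional <=98 bp "open" cutoff.
"""

import embryoatac as ea
from embryoatac.mixture import fit_length_mixture

genome = ea.make_genome(ea.GenomeConfig(), seed=1)
spec = ea.SampleSpec("diploid", 13, 6.0, "interphase", 100_000, seed=2)
library = ea.sample_fragments(genome, spec)

open_fs, nucleosomal_fs = ea.split_by_length(library, cutoff=98)
print(f"library: {len(library)} fragments")
print(f"open (<=98 bp): {len(open_fs)}   nucleosomal (>98 bp): {len(nucleosomal_fs)}")

fit = fit_length_mixture(library.lengths, n_gaussians=2)
print(f"fitted exponential scale: {1 / fit.exp_rate:.1f} bp")
print(f"fitted nucleosomal means: {fit.gaussian_means.round(1)} bp")
print(f"component weights (open, mono, di): {fit.weights.round(3)}")
print(f"open/nucleosomal density crossover: {fit.crossover:.1f} bp")
print("-> the crossover lands just above the conventional 98 bp cutoff, so")
print("   the <=98 bp fraction conservatively isolates accessible DNA.")
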