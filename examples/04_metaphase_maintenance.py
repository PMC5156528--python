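"""Fraction of accessible peaks maintained through mitotic metaphase.

Mitotic chromatin condensation does not erase accessibility: peaks called
from metaphase-staged samples are compared against interphase calls, per
cycle, to measure the maintained fraction.
"""

import embryoatac as ea

genome = ea.make_genome(
    ea.GenomeConfig(chrom_sizes={"chrA": 2_500_000, "chrB": 2_500_000},
                    n_truth_peaks=1000, min_peak_gap=800,
                    metaphase_persistent_prob=0.75),
    seed=17,
)
inter = ea.sample_fragments(genome, ea.SampleSpec("diploid", 13, 6.0, "interphase", 150_000, seed=18))
meta = ea.sample_fragments(genome, ea.SampleSpec("diploid", 13, 18.0, "metaphase", 150_000, seed=19))

open_i, _ = ea.split_by_length(inter)
open_m, _ = ea.split_by_length(meta)
peaks_i = ea.call_peaks(open_i, genome.chrom_sizes)
peaks_m = ea.call_peaks(open_m, genome.chrom_sizes)
print(f"interphase peaks: {len(peaks_i)}   metaphase peaks: {len(peaks_m)}")

out = ea.metaphase_maintenance({13: peaks_i}, {13: peaks_m})
frac = out.loc[0, "fraction"]
print(f"fraction of interphase peaks still accessible at metaphase: {100 * frac:.1f}%")
print("-> close to the generator's planted persistence probability (75%),")
print("   mirroring the majority-maintained behavior seen genome-wide in embryos.")
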