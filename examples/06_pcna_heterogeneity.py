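"""Estimate S-phase activity from replication-focus texture.

During S phase, PCNA concentrates into punctate replication foci. Per
nucleus and frame, fluorescence is quantized to six gray levels and a
co-occurrence matrix over eight radial offsets yields heterogeneity =
1 - homogeneity; scaling by relative mean intensity estimates the fraction
of signal in focal form.
"""

import numpy as np
from scipy.stats import spearmanr

import embryoatac as ea
from embryoatac.synthetic import default_focal_trajectory

trajectory = default_focal_trajectory(n_frames=16, peak=0.5)
stack, masks, truth = ea.make_pcna_movie(
    ea.ImageSpec(n_frames=16, focal_fraction=trajectory), seed=4
)
print(f"movie: {stack.shape[0]} frames, {masks.max()} nuclei")

profile = ea.sphase_profile(stack, masks)
print("\nframe  truth_focal  mean_scaled_het   sd")
for _, row in profile.iterrows():
    t = int(row["frame"])
    print(f"{t:5d}  {truth[t]:11.2f}  {row['mean_scaled_heterogeneity']:15.3f}  {row['sd']:.3f}")

rho = spearmanr(profile["mean_scaled_heterogeneity"], truth).statistic
peak_frame = int(profile["mean_scaled_heterogeneity"].idxmax())
print(f"\nSpearman(profile, planted trajectory) = {rho:.2f}")
print(f"profile peak at frame {peak_frame}, planted peak at frame {int(np.argmax(truth))}")
print("-> the scaled heterogeneity profile rises and falls with replication")
print("   activity, usable as an S-phase timer alongside the ATAC timecourse.")
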