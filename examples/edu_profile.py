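"""Locate the ring of proliferating cells relative to the tissue boundary.

Builds a cohort of five synthetic EdU/Sox2 image pairs whose punctate EdU
signal sits 15 px inside the epithelial outline, then runs the averaging /
outline / strip-profiling procedure and reports where the EdU density peaks.
A negative peak distance means proliferation concentrates just inside the
organ's boundary.
"""

from utrisim.edu import ImagePair, profile_pipeline
from utrisim.synth import gen_edu_images

pairs, truth = gen_edu_images(n_images=5, ring_offset=15.0, seed=0)
profile, outline, averaged = profile_pipeline(
    [ImagePair(edu, sox2) for edu, sox2 in pairs], strip_length=120
)

print(f"true ring offset: {truth['ring_offset']:.0f} px inside the boundary")
print(f"profile peak at {profile.peak_distance:+.1f} px "
      f"(negative = inside), from {profile.n_strips} strips")
peak = profile.mean.max()
edge = profile.mean[-1]
print(f"peak intensity {peak:.1f} vs outside-the-boundary level {edge:.1f}")
print("The peak just inside the outline reproduces the proliferation ring.")
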