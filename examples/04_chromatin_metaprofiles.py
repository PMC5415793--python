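"""Allelic chromatin metaprofiles around TSSs, grouped by gene class.

Builds a synthetic inactive-X signal track whose TSS peak is twice as high
at derepressed genes as at silenced ones, then recovers that contrast with
the 500-bp-section TSS metaprofile (40 sections spanning +/- 10 kb, averaged
from the native 50-bp bins, strand-aware).
"""

from allelix import SimConfig, profile_by_class, simulate_dataset, tss_metaprofile
from allelix.simulate import simulate_signal_tracks

ds = simulate_dataset(SimConfig(seed=1))
track = simulate_signal_tracks(
    ds, amplitudes={"silenced": 1.0, "derepressed": 2.0, "escapee": 0.5}
)
prof = tss_metaprofile(track, ds.genes)
print(f"profile matrix: {prof.matrix.shape[0]} genes x "
      f"{prof.matrix.shape[1]} sections of 500 bp")

by_class, sizes = profile_by_class(
    prof, ds.truth["true_class"].reindex(prof.matrix.index)
)
tss_bin = 0  # section starting at the TSS
print("\nmean signal in the first downstream section, per class:")
for cls in by_class.index:
    print(f"  {cls:>12} (n={sizes[cls]:3d}): {by_class.loc[cls, tss_bin]:.2f}")
print("\nThe derepressed class shows the elevated TSS signal it was built "
      "with - the same readout used on real allelic ChIP-seq tracks to ask "
      "whether open/active chromatin marks predict derepression.")
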