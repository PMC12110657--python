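"""Build the bilateral 3x5 probe montage and inspect its channel map.

Two arrays of 8 emitters + 7 detectors give 22 source-detector channels
per hemisphere. Four channels localized outside the cranial boundary are
excluded, and the remaining 40 are reordered into eight region groups
(frontal / motor / parietal / temporal, per hemisphere) — the ordering
used for every connectivity matrix axis.
"""

from fnirspeech.montage import paper_montage, region_ordered_ids

cmap = paper_montage()
print(f"channels: {cmap.n_channels} total, {cmap.n_valid} valid "
      f"(excluded: {sorted(cmap.excluded_ids)})")

ids = region_ordered_ids(cmap)
print(f"region-ordered axis, first positions: {ids[:6]}")
for region, members in cmap.region_groups:
    print(f"  {region:15s} {list(members)}")

# The counts are pure montage arithmetic: 2 x (3*4 + 2*5) = 44 adjacent
# emitter-detector pairs, minus the 4 excluded channels = 40 analyzed.
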