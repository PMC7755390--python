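"""Score where a tagged protein lives: cell bodies or the neuropil.

Renders a scene whose tag channel is confined to somata, segments somata
(low threshold + area gate) and neuropil (high threshold minus somata)
from the surface-reporter channel, thresholds the tag channel with
IsoData, and prints the two localization percentages.
"""

import synquant as sq

spec = sq.SceneSpec(frame_px=256, n_somata=3, seed=8, tag_compartment="soma")
channels, truth = sq.generate_scene(spec)  # default noise, SNR ~ 8

surface = channels["surface_reporter"]
somas = sq.segment_somata(surface, spec.suggested_soma_threshold,
                          min_soma_area_um2=10.0)
neuropil = sq.segment_neuropil(surface, spec.suggested_neuropil_threshold, somas)

tag_threshold = sq.threshold_isodata(channels["tag"])
tag_mask = channels["tag"].pixels >= tag_threshold

pct_somas = sq.score_soma_tag(somas, tag_mask, min_tag_overlap_um2=0.05)
pct_neuropil = sq.score_neuropil_tag(neuropil, tag_mask)
print(f"tag-positive somas: {pct_somas:.1f}% of {len(somas)}")
print(f"neuropil covered by tag: {pct_neuropil:.2f}%")
# With the tag planted only in cell bodies, the somatic score reaches
# 100% while neuropil colocalization stays at the noise floor (< 2%).
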