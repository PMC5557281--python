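"""Discard detections that fail expert criteria and erase them from the frame.

The acceptance intervals play the role of the domain expert's
"characteristics": anything outside the plausible T cell morphology or
below the calcium-activity floor is treated as noise.
"""

from ttrack import (
    FilterCriteria, SceneConfig, SegmentationConfig, activation_floor,
    apply_filter, erase_cells, generate_scene, render_timelapse, segment_frame,
)

scene = generate_scene(SceneConfig(frame_shape=(512, 512), n_frames=1,
                                   n_cells=20, seed=11))
timelapse, _ = render_timelapse(scene)
frame = timelapse.get(0)
detections = segment_frame(frame, SegmentationConfig())

floor = activation_floor(frame)
criteria = FilterCriteria(
    area=(150, 450),           # this expert calls footprints under 150 px debris
    extent=(0.4, 1.0),         # round-ish cells fill their bounding box
    require_activity=True,
    activity_floor=floor,      # background mode + 3 robust noise sigmas
)
kept, discarded = apply_filter(detections, criteria)
print(f"activity floor = {floor:.0f} intensity units")
print(f"kept {len(kept)} of {len(detections)} detections, "
      f"discarded {len(discarded)} whose features fall outside the criteria")

cleaned = erase_cells(frame, discarded)
redetect = segment_frame(cleaned, SegmentationConfig())
print(f"after erasing the discarded cells the detector finds {len(redetect)} "
      "cells: erased pixels are reset to the modal background and stay gone")
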