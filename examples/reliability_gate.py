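"""Score one segmentation against a reference with the reliability gate.

Simulates a trainee whose segmentation misses part of one nucleus and
over-paints another, then checks Dice >= 0.85 and counts within +-1.
"""

import numpy as np

from nucledit import (
    LabelVolume,
    erase,
    make_cortex_block,
    paint,
    presegment,
    reliability_check,
    render_scene,
)

spec = make_cortex_block(rng_seed=3, extent=(40.0, 48.0, 48.0))
image, _ = render_scene(spec)
reference, _ = presegment(image)

# a "trainee" copy with a few voxel-level disagreements
trainee = LabelVolume(reference.data.copy(), reference.spacing)
first = int(reference.labels()[0])
trainee = erase(trainee, first, z=reference.shape[0] // 2,
                center=(24, 24), radius=6)
trainee = paint(trainee, first, z=0, center=(5, 5), radius=3)

report = reliability_check(trainee, reference)
print(f"dice:   {report.dice:.4f} (threshold {report.dice_threshold})")
print(f"counts: {report.count_a} vs {report.count_b} "
      f"(tolerance +-{report.count_tolerance})")
print(f"passed: {report.passed}")
# The gate passes only when both the voxel-overlap Dice and the nucleus
# counts agree - the same double criterion used to certify annotators
# before they contribute training labels.
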