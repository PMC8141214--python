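"""A scripted editing session: paint, grow, merge, and track progress.

Shows the voxel- and region-level edits on a small synthetic scene, with
the JSON-backed metadata recording modified/done status throughout.
"""

import numpy as np

from nucledit import (
    RegionMetadata,
    build_region_table,
    grow_region,
    mark_done,
    merge_regions,
    paint,
    presegment,
    make_touching_cluster,
    render_scene,
)

spec = make_touching_cluster(k=2, overlap=0.3, rng_seed=1)
image, _ = render_scene(spec)
labels, _ = presegment(image)
meta = RegionMetadata()

# brush in a missing patch of label 1 on the middle slice
z = labels.shape[0] // 2
labels = paint(labels, 1, z=z, center=(4, 4), radius=2, meta=meta)

# grow label 1 toward a dim shoulder the threshold missed
region_slice = np.argwhere(labels.data[z] == 1)
y, x = region_slice[0]
target = (z, max(int(y) - 2, 0), int(x))
if labels.data[target] == 0:
    labels = grow_region(image, labels, 1, target, meta=meta)

# add a second region by painting, then merge it into label 1
new_label = int(labels.data.max()) + 1
labels = paint(labels, new_label, z=z, center=(2, 2), radius=1, meta=meta)
labels = merge_regions(labels, 1, new_label, meta=meta)

mark_done(meta, 1, True, labels)

table = build_region_table(labels, meta).sorted("size", descending=True)
print("label\tsize\tdone\tmodified")
for rec in table:
    print(f"{rec.label}\t{rec.size}\t{rec.done}\t{rec.modified}")
# 'modified' tracks unsaved edits per region; 'done' is the annotator's own
# progress mark. Both persist in the JSON sidecar written next to the labels.
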