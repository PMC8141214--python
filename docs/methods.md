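# Methods

This note documents the models, conventions, and numerical choices behind
`nucledit`, and what the synthetic benchmarks do and do not demonstrate.

## Data model and conventions

Volumes are dense `(z, y, x)` arrays; the microscope's X–Y plane is the last
two axes. Voxel spacing is `(dz, dy, dx)` in µm, defaulting to
(2.50, 0.75, 0.75) — the acquisition geometry of the light-sheet stacks the
tool targets. NIfTI files carry spacing in their header (data are stored
x-fastest and transposed on read); TIFF has no reliable spacing convention,
so TIFF reads use the default unless overridden. Multi-file TIFF stacks are
ordered by plain lexicographic filename sort: deterministic and easy to
reason about, at the cost of requiring zero-padded slice numbers.

Label volumes use 0 for background and any positive integer per instance.
On write, labels are stored in the smallest unsigned dtype that holds the
maximum label. Per-region *modified*/*done* flags live in a JSON sidecar
(`<labels>.regions.json`, schema `{"version": 1, "regions": {"<label>":
{"modified": bool, "done": bool}}}`); unknown keys round-trip untouched so
other tools can annotate the same file. The schema is this package's own
dialect — no compatibility with any other tool's metadata is claimed.

## Pre-segmentation

Otsu's threshold is computed over a 256-bin histogram of the full volume
(`skimage.filters.threshold_otsu` on an explicitly built histogram).
Foreground is `intensity ≥ threshold`: the ≥ convention keeps boundary
voxels exactly at the threshold inside the mask and is applied consistently
everywhere a threshold appears (pre-segmentation, split seed masks). A
constant volume has no threshold and is rejected rather than guessed at.

Connected components use 26-connectivity by default: nuclei are blob-like,
and face-only connectivity fragments diagonal contacts; 6-connectivity is
available everywhere via a parameter. Connectivity is defined on the voxel
grid and ignores physical anisotropy — the standard labeling semantics;
anisotropy matters only where physical distances are computed (the
generator's geometry). Components are numbered 1..K by the raster order of
each component's first voxel, making label assignment reproducible and
directly comparable with a naive flood-fill oracle. No minimum-size
filtering is applied; noise specks are left for downstream editing.

## Editing operations

**Brush.** Paint/erase act on one Z-slice with a circular footprint: voxel
centers within Euclidean `radius` (voxel units, in-plane) of the brush
center. Painting is authoritative and reassigns other regions' voxels
(flagging them modified); erasing only clears the selected label.

**Grow/shrink.** Both operate strictly within the selected voxel's Z-slice,
where resolution is finest (0.75 µm vs 2.50 µm axially), with in-plane
8-connectivity. Grow adds background voxels with intensity ≥ the selected
voxel's, no farther from the region (nearest-voxel Euclidean distance, in
plane) than the selection, and reachable from the region through the
eligible set. "No farther than the selected voxel" is measured to the
nearest region voxel rather than to the region boundary — the simpler and,
for a selection outside the region, more natural reading. Grow never annexes
other labels. Shrink mirrors it inside the region: it removes voxels with
intensity ≤ the selection that lie no deeper (distance to the region's
complement; the volume edge counts as complement) and are reachable from
the region's boundary. Grow and shrink are not exact inverses: grow adds
the ≥-t set, shrink removes the ≤-t set, so a grow-then-shrink at one voxel
re-removes only the dimmest of the grown voxels.

**Merge.** Reassigns every voxel of the source label to the target;
metadata drops the source entry. Total labeled voxel count is conserved and
the region count drops by exactly one.

**Split.** See the README for the algorithm. Numerical choices:

- The threshold sweep enumerates the region's *distinct* intensity values —
  exact, finite, and independent of intensity resolution.
- Ties in the max-min-component criterion go to the lowest threshold
  (larger, more conservative seeds).
- The largest seed keeps the source label; the others get fresh labels
  above the current volume maximum (stable bookkeeping for the sidecar).
- Growth exhausts each intensity level (repeated simultaneous one-voxel
  dilation passes until nothing at the working intensity is claimable)
  before stepping down. A single dilation per level would make the
  partition depend on how finely intensities are quantized — rescaling a
  volume from 8-bit to 16-bit would change the result — whereas
  level-exhausting growth is quantization-invariant and behaves like
  marker-based flooding from the seeds.
- Conflicts (one voxel adjacent to several fronts in the same pass) go to
  the front whose claiming neighbor is brightest, ties to the lowest seed
  index: deterministic, and favoring the front with more local evidence.
- After the lowest level, passes repeat until fixpoint, so every voxel of a
  connected source region is claimed (`unassigned_count = 0`); a
  disconnected source can leave seedless islands unclaimed, reported in the
  result.
- If no threshold yields exactly *n* components the split raises and the
  volume is untouched; constant-intensity regions are the canonical case.

## Reliability and case-study statistics

Dice is computed on binarized foregrounds (any label > 0): the training
workflow compares whole segmentations between raters, and one number per
image pair is what the gate consumes. Two empty masks score 1.0 by
convention. A matched per-region Dice (greedy max-overlap label matching)
is available for diagnostics but is not the gate. The gate passes iff
Dice ≥ 0.85 *and* the nucleus counts agree within ±1 — both defaults
configurable.

Timing comparisons use a two-tailed paired t-test with a Student-t 95% CI
on the mean difference (n − 1 df). Degenerate inputs are handled explicitly:
all-zero differences report t = 0, p = 1; a nonzero constant difference
reports infinite t, p = 0, and a point CI. Percent reduction
`100·(mean_a − mean_b)/mean_a` is reported to one decimal; p-values to five
significant figures; no multiple-testing correction is applied. Timing
tables are two-column TSV (image-id, minutes) aligned on image id.

## Synthetic scenes

The generator emulates the statistics that matter to the editing
operations, not the optics. Each nucleus is an anisotropic Gaussian
intensity profile `peak · exp(−½ Σ ((p−c)/σ)²)` with `σ = falloff · radius`
per axis — brightest at the center, the premise the split relies on.
Defaults: radius 3.5 µm (a ≈ 7 µm cortical nucleus), peak 200, falloff 0.5,
background 10, additive Gaussian noise SD 5 clipped at zero, quantized to
uint16 as camera data would be. Ground truth assigns a voxel to the nucleus
with the largest *peak-normalized* profile, provided that profile exceeds
half its value at the nominal radius (cutoff `0.5·exp(−0.5/falloff²)`,
configurable in principle via the falloff); the supports of nearby nuclei
overlap, and the argmax draws the boundary at the profile bisector.

`make_touching_cluster` places k ∈ {2, 3} equal-radius nuclei with adjacent
centers at `(1 − overlap)·(rᵢ + rⱼ)` (a line for k = 2, an equilateral
in-plane triangle for k = 3; default overlap 0.3), so Otsu's threshold of
the rendered scene joins them into one region while each keeps a brighter
core. All nuclei in a cluster share the default peak: the ground truth is
peak-normalized, so unequal peaks would put the true boundary off the
intensity ridge and no intensity-driven method could be scored against it
fairly. `make_cortex_block` draws a Poisson number of nuclei at the
empirical cortical density (~460 per 96 × 96 × 160 µm block), with mild
radius and peak variation, uniform centers, overlaps allowed.

Deliberately not modeled: the light-sheet PSF, stripe artifacts,
vignetting, Poisson shot noise, intensity inhomogeneity across depth.
Passing the synthetic benchmarks therefore shows the algorithms do what
they claim on bright-centered blob instances with realistic geometry and
additive noise — not that any particular real acquisition will split
perfectly.

## Benchmark design and observed behavior

Split recovery is measured per ground-truth nucleus over its voxels
*within the split source region*: the split cannot assign voxels it was
not given, and the ground-truth support intentionally extends below the
pre-segmentation threshold. The recovery criterion (≥ 90% of each
nucleus's voxels in one output region, 20 seeded clusters per k) passes
with margin — worst per-nucleus recovery 0.95 for k = 2 and 0.905 for
k = 3 on the benchmark seeds. On a wider 60-seed scan one k = 3 cluster
dips to 0.85 where marker-based watershed from the same seeds reaches
0.95: within one intensity level the fronts advance in synchronized
one-voxel passes rather than in strict per-voxel intensity order, so a
front can occasionally cross a shallow valley it should lose. This
residual difference from true priority-flood ordering is a known
limitation; the three-way boundary zone of triangular clusters on ~80-voxel
nuclei is where it shows.

Test problem sizes (random volumes ≤ 16³ against a Python flood-fill
oracle, ≤ 12³ regions against an exhaustive threshold search, 20 cluster
fixtures per k) keep the full suite under ten seconds while exercising
every code path; the oracles are deliberately naive re-implementations that
share no code with the package.

## Known limitations

- Volumes are held in memory; no chunked or pyramidal access.
- VTI, HDF5, and OME-Zarr are out of scope; TIFF and NIfTI cover
  interchange.
- The split assumes nuclei brighter at the center than at contact
  surfaces; inverted or ring-stained signals will defeat the seed search.
- Grow/shrink are single-slice by design; there is no 3D brush.
- No undo stack: operations are functional (each returns a new volume), so
  callers keep history if they need it.
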