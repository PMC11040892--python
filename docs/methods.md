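# Methods

## The scoring problem

The in vitro micronucleus assay scores chromosomal damage by the fraction
of interphase cells whose cytoplasm contains, besides the main nucleus,
one or more micronuclei — small chromatin bodies left out of the nucleus
at division.  With acridine orange (AO) staining under blue excitation,
nuclear material fluoresces green and cytoplasm red, so a color micrograph
carries the segmentation problem in its channels: green blobs are nuclei
or micronuclei, and the red plane outlines cytoplasm.  `mncount`
automates the per-image counting of total cells and micronucleated (MN)
cells from folders of such micrographs.

## Pipeline

For one image with parameters `(binarization_th, kernel_s, kernel_l,
noise_reduction, micronucleus_th, window_level, sigmoid_gain)`:

1. **Channel split.** The RGB image is split; blue is discarded.
2. **Green binarization.** `pixel >= binarization_th` (the `>=`
   convention is fixed so a pixel exactly at the threshold is foreground).
3. **Cleanup.** Opening then closing with a `kernel_s × kernel_s` square
   element removes speckle and fills pinholes.  Outside the frame counts
   as background for both the min and the max half of each operator, so
   the operators equal sliding-window min/max filters under zero padding.
4. **Size classification by erosion.** The cleaned mask is eroded with a
   `kernel_l × kernel_l` square.  An 8-connected component with a
   surviving remnant is a nucleus and is restored to its full original
   extent (reconstruction by component membership); a component that
   erodes away entirely is a micronucleus candidate.  The two outputs
   partition the cleaned mask exactly.  A disk survives erosion by a
   `k × k` square iff its radius reaches the square's half-diagonal,
   `r ≥ (k−1)/2·√2` (plus up to ~0.5 px for sub-pixel disk centers), which
   is the geometric content of the size cut.
5. **Candidate filtering.** Candidates are measured (area `A`, outer
   boundary chain perimeter `P`, centroid, circularity
   `c = min(1, 4πA/P²)`) and kept when `A ≥ noise_reduction` and
   `c ≥ micronucleus_th`.  The perimeter is the closed 8-connected
   Moore-boundary chain with orthogonal steps of 1 and diagonal steps of
   √2; a single pixel has `P = 0` and `c = 1` by convention.  Chain
   perimeters underestimate the true perimeter of digital disks, which is
   why circularity is clipped at 1 — round spots should sit at the top of
   the scale, as the threshold semantics ("1 accepts only perfect
   circles") require.
6. **Cytoplasm recovery.** The red and green channels are superimposed by
   per-pixel maximum, passed through the sigmoid gradation
   `s(v) = round(255/(1+exp(−g(v−c))))` centered at `window_level` with
   gain `g = sigmoid_gain`, thresholded by Otsu's method (foreground
   strictly above the Otsu value, skimage's convention), cleaned, and
   hole-filled so nuclei lie inside the cytoplasm mask.
7. **Cell separation.** Marker-controlled watershed on the negated
   Euclidean distance transform of the cytoplasm mask, markers = restored
   nucleus components, with watershed lines excluded from every cell.
   Cytoplasm components without a nucleus are not cells (debris/ghosts);
   components holding k nuclei split into k cells along lines near the
   midlines between nuclei.
8. **Classification.** Each accepted micronucleus is assigned to the cell
   label containing its centroid; centroids on background or watershed
   lines are discarded.  A cell with ≥ 1 assigned micronucleus is one MN
   cell however many micronuclei it holds.  Cells touching the image
   border are counted by default (the whole imaged field is scored);
   `exclude_border=True` drops cells within a 2 px border band — a band,
   not a line, because the cleanup's outside-is-background semantics
   cannot keep foreground on the outermost pixel ring.

## Parameters

| parameter | meaning | default / rule |
|---|---|---|
| `binarization_th` | green cutoff separating nuclear material from background/cytoplasm | auto: one of 65/75/85/120/165 |
| `kernel_s` | cleanup square width (px) | 3 |
| `kernel_l` | erosion square width (px) setting the nucleus/MN size cut | odd ≥ max(7, round(0.6·d̂)) |
| `noise_reduction` | minimum candidate area (px²) | 11 if `kernel_l ≤ 15` else 21 |
| `micronucleus_th` | circularity acceptance threshold | 0.5 (practically tuned 0.6–0.7) |
| `window_level` | sigmoid center intensity | 118 |
| `sigmoid_gain` | sigmoid steepness (per intensity unit) | 0.05, config-level |

**Automatic binarization TH.** The modal nonzero green intensity (bin 0
excluded; ties break low) is mapped monotonically onto the five
representative levels: peak < 50 → 65, 50–69 → 75, 70–99 → 85,
100–149 → 120, ≥ 150 → 165.  The five levels are fixed by the method; the
bin edges are this package's own calibration and are config-overridable.
A blank image warns and falls back to 65.

**Nucleus-size pre-pass.** `d̂` is the area-weighted median equivalent
diameter (`sqrt(4A/π)`) of 8-connected components larger than 50 px² in
the green channel binarized at Otsu's threshold.  Weighting by area is
deliberate: with few cells in the field plus several micronucleus- or
debris-sized blobs above the 50 px² floor, the unweighted median can land
between the two size clusters and request a kernel too small to separate
nuclei from micronuclei, while the nuclei always dominate green
foreground *area*.  Degenerate frames (constant, mostly-foreground, or
nothing above the floor) fall back to d̂ = 20 px with a warning, and the
estimate is clipped to [6, 80] px.

**Parameter files.** Each image's six values are stored one per line in
the fixed order binarization TH, kernel S, kernel L, noise reduction,
micronucleus TH, window level — the same dialect for per-image `Palam`
files and the `PalamLock.txt` that drives batch reanalysis.  The sigmoid
gain stays out of the file to preserve the six-line format.

## Workflows

*Initial analysis* walks a folder in filename order, derives each image's
parameters automatically, writes the six-folder results tree (`Image`,
`Grayscale`, `Count`, `Shokaku`, `Text`, `Palam`), one Palam file per
image, and a `PalamLock.txt` seeded from the first image's parameters
(the natural seed for later batch runs).  *Individual reanalysis* merges
explicit overrides onto one image's stored parameters and rewrites only
that image's artifacts.  *Batch reanalysis* re-runs the folder with the
single PalamLock set and overwrites every per-image Palam file with it.
All three are deterministic: identical inputs give byte-identical text
artifacts, and batch with an unchanged PalamLock is idempotent.

## Synthetic scenes

The generator renders what the detector assumes: elliptical red-dominant
cytoplasm (semi-axes ~26–38 px), one concentric bright-green nucleus disk
per cell, optional green micronucleus disks in the cytoplasm, optional
elongated green debris streaks, per-pixel Gaussian staining texture and
additive sensor noise, at an emulated 20×-objective scale on a flat
background.  Default intensities: background 5; cytoplasm red 140 ± 15
with green bleed 40 ± 10; nucleus/MN green 200 ± 15 with red bleed
30 ± 8; noise σ 5 — chosen so the automatic binarization lands at the
lowest level and the sigmoid at 118 cleanly separates cytoplasm from
background.  Same seed, same pixels.

Three geometric defaults are pinned to the method's own constants rather
than chosen freely:

- **Nucleus radii 12.2–14 px.**  The kernel rule ties `kernel_l` to the
  median nucleus diameter, and erosion survival needs
  `r ≥ (k−1)/2·√2 + 0.5`.  For this band the rule yields `kernel_l` ∈
  {15, 17} and every nucleus clears the survival bound at either kernel;
  a wider radius band makes the smallest nuclei in a field fall below the
  bound of the kernel the field's own median demands — the method, not
  the implementation, misclassifies them.
- **Micronucleus radii 3–4.5 px.**  The same rule selects noise floor
  21 px² when `kernel_l > 15`, and a disk needs radius ≥ ~2.8 px to
  rasterize to 21 px; smaller micronuclei are sub-floor by definition.
  The upper end stays far below the erosion survival bound.
- **Micronucleus clearance 5 px from the nucleus boundary.**  The 3×3
  closing (1 px reach) plus rasterization and noise roughness of the
  nucleus rim (~1–2 px) can bridge smaller gaps and merge the
  micronucleus into the nucleus component — the method's documented
  close-contact blind spot.  The generator places micronuclei outside
  that blind spot so recovery tests measure the pipeline, not the blind
  spot.  (The stored truth invariant — MN center ≥ 2 px outside the
  nucleus disk — is implied.)

Debris streaks are rotated rectangles, width 4–4.5 px and elongation
4.5–5.5, rendered at nuclear intensity inside a cell's cytoplasm: wide
enough to survive the 3×3 opening intact (3 px streaks fragment into
small near-round blobs), elongated enough that their chain circularity
stays around 0.3–0.55, safely below the 0.6–0.7 tuning range while often
above the 0.5 default — exactly the false-positive bait the circularity
threshold exists for.

Cells are placed by rejection sampling with a conservative separation
rule (center distance ≥ sum of semi-major axes + 5 px), which guarantees
disjoint cytoplasm; with clustering probability `p`, a new cell is placed
tangent to an existing one (support-radius contact with 2 px overlap) so
touching pairs exercise the watershed.  A scene that cannot be placed
raises a placement error suggesting lower density.

**What the generator does not emulate:** uneven illumination, focus
blur/PSF, staining gradients within a cell, overlapping (not merely
touching) cells, yellow double-stained granules, and nucleus shape
variation.  Exact-recovery results on synthetic scenes therefore
demonstrate the correctness of the operators and their composition, not
field performance on real slides, where staining quality dominates and
the reanalysis thresholds exist precisely because automatic parameters
are imperfect.

## Statistics

MN% = `round(100·mn/total, 2)`.  Relative viability =
`round(100·(group cells/image)/(control cells/image))`, half-up to an
integer — this reproduces every fully printed viability cell of the
bundled CHL/IU reference dataset from its raw counts.  Method comparisons
use the pooled-variance (classic Student) two-sample t-test, one-sided,
with the direction an explicit argument (default: first sample
over-calls); zero pooled variance with equal means returns t = 0,
p = 0.5.  Stars follow p < 0.05 (*), < 0.01 (**), < 0.005 (***).  The
coefficient of determination is the squared Pearson correlation and is
undefined (error) for constant series.

## Numerical choices and degenerate inputs

- 16-bit inputs map to 8-bit by integer division by 257 (full-range
  linear); other depths are rejected.
- Half-up rounding (`floor(x+0.5)`) wherever a printed integer or kernel
  size is derived, so results do not depend on banker's rounding.
- `measure_regions` accepts a boolean mask (labeled 8-connectedly) or a
  label map; regions are traced clockwise from the topmost-leftmost
  pixel, whose west neighbor is provably background.
- Watershed, labeling and all filters are deterministic; re-running an
  analysis is bit-identical, which the tests assert at the byte level on
  the text artifacts.
- Blank or constant images analyze to zero cells with warnings rather
  than errors; empty folders and unreadable files are errors, and a
  partially corrupt folder is processed with the failures logged and
  reported.

## Known limitations

- Micronuclei touching or overlapping the nucleus merge into it during
  cleanup/erosion and cannot be detected; they are accepted as missed.
- The circularity of very small candidates saturates at 1, so the
  circularity threshold cannot distinguish among spots below ~20 px².
- Batch reanalysis imposes one binarization TH on images that may have
  been auto-assigned different ones; it is intended for folders of
  consistently stained images.
- The CBMN variant (nucleus shape classes, binucleated cells) is out of
  scope, as are stain-quality correction and illumination flattening.
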