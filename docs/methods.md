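# Methods

`fluorodroplet` quantifies overlaid brightfield + fluorescence micrographs
of a microfluidic droplet trapping array: water-in-oil droplets of radius
25–50 µm held on a hexagonal lattice of traps (35 µm trap radius, 360 µm
pitch), each potentially containing fluorescent cells, rare-earth-doped
nanoparticle (NP) clusters used as droplet trackers, and debris. This note
describes the models and numerical choices; empirical behavior is
established by the test suite and `scripts/acceptance.py`, not restated
here.

## Processing domain

All analysis happens on 16-bit, 3-channel (B, G, R) pixel grids. 8-bit
inputs are lifted by ×257 so both extremes map exactly (0→0, 255→65535);
the published 8-bit color windows are lifted the same way, keeping the
inclusive interval test exact in the 16-bit domain. Grayscale conversion
uses Rec. 601 luminance (0.114 B + 0.587 G + 0.299 R). Batch order is
lexicographic by filename, which defines the image index in every output
table.

## Droplet detection

1. **Median smoothing** (square kernel, edge-replicated borders). Default
   kernel 3 px: large enough to suppress shot noise, small enough not to
   erase a 2–3 px bright droplet rim. Configurable.
2. **Edge extraction** inside the CHT: Sobel gradient magnitude,
   hysteresis thresholding with high = Otsu level of the magnitude and
   low = high/2. Otsu is used because the rim-to-background contrast is
   strongly bimodal, making the split insensitive to illumination level.
3. **Gradient voting.** Each edge pixel votes at
   (a, b) = (x ∓ R cos θ, y ∓ R sin θ) for every candidate radius
   R ∈ [r_min, r_max] (step 1 px), θ being the local gradient direction.
   Voting along ±∇g only (rather than full circles) keeps the accumulator
   two-dimensional and suppresses the spurious inter-circle peaks that
   full-circle voting produces — the classic weakness of naive
   accumulation. Implementation detail: votes from all radii share one
   (a, b) plane; because a circle's center receives its perimeter votes at
   the *same* (a, b) for every radius bin, the collapsed plane has the
   same peak set as per-radius accumulators while avoiding a 3-D array.
4. **Peak extraction.** The plane is 3×3 box-summed (votes scatter ±1 px
   through gradient-angle rounding), thresholded at
   `vote_threshold_frac · 2π·r_min`, and candidates are accepted by greedy
   non-maximum suppression (highest votes first; ties broken toward
   smaller (row, col); minimum separation 2·r_min by default).
5. **Radius recovery.** Per accepted center, the radial histogram of edge
   pixel distances is formed; the radius is the vote-weighted mean of all
   bins holding ≥ 50 % of the peak bin. A rim of finite thickness yields
   two thin edge rings (inner/outer); the weighted mean recovers the
   mid-rim radius to ~1 px where either ring alone would bias by the
   half-thickness. The detection is kept only if the peak bin reaches
   `vote_threshold_frac · 2πR` supporting pixels (default fraction 0.4, an
   engineering default validated by the noiseless recovery tests).
6. **Trap deduplication.** Detections closer than 2·r_max are one physical
   trap; the highest-vote member survives. Optional lattice validation
   compares surviving nearest-neighbor spacings against 360 ± 10 µm and
   logs (never removes) violations, since partially filled arrays
   legitimately break equidistance.

Centers are integer pixels; no sub-pixel refinement is attempted. The
default calibration is 1 µm/px, at which the micron-valued parameters
(25/50 µm radii, 360 µm pitch) equal their pixel-valued counterparts.

## Contour detection

Per fluorophore class (inclusive 8-bit B,G,R windows; defaults: live
[0,51,0]–[153,255,153], dead [0,0,51]–[153,153,255], overlap
[0,51,51]–[153,255,255], Eu-NP [51,0,51]–[255,102,255], Tb-NP
[51,0,0]–[255,51,51]):

color mask → masked luminance (median smoothed, kernel 3) → Canny
(σ = 1; thresholds default to Otsu-of-gradient high, half that low) →
dilation → erosion (3×3 square, 1 iteration each: dilation closes broken
edge chains, erosion removes speckle and detaches touching chains) →
interior fill → random-walker splitting → contour extraction → area
threshold (≥ 130 px² cells, ≥ 150 px² NP clusters, both inclusive).

Design choices worth calling out:

* **Random-walker markers** are local maxima of the Euclidean distance
  transform with minimum separation √(min_area_cell/π) (the radius of the
  smallest admissible cell). The walker (β = 130) runs only on connected
  components with ≥ 2 markers, on the normalized distance transform; for
  symmetric touching objects the probability boundary is the
  perpendicular bisector.
* **Pixel membership.** Edge tracing localizes a boundary only to ~±1 px;
  taken literally, the filled edge map would bias areas by a boundary
  ring (~40 px² on a 140 px² cell) — material next to the 130/150 px²
  thresholds — and dilute single-channel means with rim background. The
  final pixel set of a contour is therefore the color mask itself,
  partitioned among segmentation labels (nearest label within 3 px; mask
  speckle farther than that is dropped). The mask is the
  fluorescence-positive region by definition, so areas and intensities
  are measured on signal pixels only.
* **Convex-hull adjustment.** The traced boundary polygon is replaced by
  its convex hull when the deepest convexity defect exceeds 3 px (pixel
  set and area are never altered — only the reported outline).
* **Conflict resolution.** Class passes run independently; detections of
  one physical region (centroid distance < 5 px) are reported once under
  the precedence overlap > dead > live > Eu-NP > Tb-NP, so dual-signal
  ("dying") cells are captured by the overlap class instead of being
  counted as both live and dead.
* **Locality.** After the full-frame color mask, per-class processing runs
  on padded bounding boxes of mask components. Components are processed
  independently in either formulation, so results are identical, but cost
  scales with fluorescent signal rather than sensor area.

## Encapsulation and tracking

A contour belongs to a droplet iff its centroid lies within the droplet's
*detected* radius (tighter and more consistent than a fixed 50 px scan);
nearest center wins ties, then lower droplet id. Unassigned contours are
free-floating and excluded from population statistics. Occupancy counts
cell classes only (empty / single-cell / multi-cell); NP clusters never
contribute to occupancy but define the tracked (co-encapsulated) flag and
the subpopulation table (empty / cell-only / NP-only / co-SC / co-MC).
The identities `empty + SCE + MCE = droplets` and
`assigned + free = contours` hold structurally.

## Intensity quantification

Statistics (mean, min, max, variance) are computed over the contour pixel
set on the class's fluorescence grayscale — live → G, dead → R, overlap →
(G+R)/2, Eu-NP → (B+R)/2, Tb-NP → B — not on composite luminance, since
uptake signals are single-channel. Variance is population (÷n) by
default; sample (÷(n−1)) is configurable. Background is the median of
in-droplet, non-contour pixels (whole-image non-contour median when no
droplets are present), and normalization is the ratio mean/background
(subtraction available), making normalized values scale-invariant. The
distribution histogram uses 256 uniform bins over [0, 65536) — 8-bit
binning of the 16-bit range — annotated with the 16-bit extremes and
variance.

## Synthetic scenes

The generator renders what the detector consumes: a flat background
(5000 gray units), droplets as slightly brighter interiors with a bright
rim annulus ~3 px thick at the true radius (brightfield rims are the only
droplet signature the CHT sees; full photometric modeling is out of
scope), and objects as filled colored disks. Defaults encode the study
conditions: hexagonal lattice at 360 µm pitch, droplet radii uniform in
[25, 50] px, cell areas ~N(140, 10²) px² floored at 132, NP areas
~N(170, 10²) floored at 152, debris 20–90 px², occupancy 0–3 cells per
droplet, Gaussian read noise σ = 800 (σ = 1200, ~3 % of mid-range signal,
in the intensity preset). The floors reflect populations in which the
130/150 px² thresholds exclude only debris — the stated rationale for
those thresholds (mean areas ~140/~170).

Object colors are sampled from the interior 50 % of each class's color
window, further clipped to the sub-box that no higher-precedence-violating
window covers: the published windows overlap on paper (magenta NP colors
can satisfy the red-cell window), and an ambiguous rendering would make
ground-truth labels meaningless. Each object's true mean intensity is
recorded in the same channel convention the pipeline measures.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: optical point-spread blur and partial-volume
boundary pixels, non-uniform illumination, autofluorescence gradients,
out-of-focus droplets, deformed (non-circular) droplets, overlapping cells
beyond simple disk contact, and JPEG compression artifacts (the effect of
lossy compression on color-window membership is undocumented and left as a
caveat). Scores on synthetic scenes are upper bounds on real-data
performance.

## Problem sizes

The validation studies are desk-scale by design: counting uses a
triplicate of 30 frames (1024², nine traps each, ≥ 275 cells per set);
tracking uses duplicate 88-frame runs (792 droplets per run, matching the
~787-droplet experiment size at whole-frame granularity); intensity uses
20 frames (≥ 142 matched cells). Each study completes in minutes on one
CPU core.

## Known limitations

* Radius estimates inherit a ±1–2 px uncertainty from rim thickness; the
  containment test uses the detected radius, so cells hugging the droplet
  boundary can in principle flip between assigned and free-floating.
* The CHT requires a roughly known radius range; arbitrarily sized or
  elliptical droplets are out of scope (ellipse transforms are a known
  alternative, not implemented).
* Color windows are axis-aligned boxes in B,G,R; spectrally overlapping
  fluorophores need user-supplied windows plus the precedence rule, and
  genuinely ambiguous colors resolve by precedence, not by spectra.
* Time-lapse identity tracking across frames is out of scope; images are
  independent.
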