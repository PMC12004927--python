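# Methods and design notes

This note records how each quantity is defined, what the synthetic scenes
do and do not emulate, and the choices made where the design was genuinely
open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Segmentation

**Histograms and thresholds.**  Intensities are kept in [0, 1]; histograms
use 256 equal-width bins (right-open, last bin closed).  When a series is
analysed over time, min–max normalization is applied per acquisition
series, not per frame, so thresholds remain comparable across time points.
Multi-level Otsu thresholds maximise the between-class variance
Σₖ ωₖ(μₖ − μ_T)², equivalently the separable score Σₖ Sₖ²/Wₖ over segment
sums of count·centre and count.  The search is exhaustive — a dynamic
programme over every placement of the k − 1 cut points — and is evaluated
in exact rational arithmetic: counts are integers and equal-width bin
centres are proportional to odd integers, so scores are exact fractions
and the argmax cannot be flipped by floating-point round-off (with 64-bit
floats, distinct placements can differ by ~1e-13 relative and round-off
does pick the wrong one on occasion).  Ties — which occur whenever empty
bins separate populations — are broken toward the lexicographically
smallest threshold tuple.  Thresholds are reported as bin upper edges.

**Class counts.**  Three classes are the default for μ-dish/μ-channel
scenes (bright background, gray cells, dark biofilm) and the pore-network
phase split also uses three classes on the non-grain pixels; both are
configuration keys, as is the band→phase map (for the rendered scenes, gas
is brightest and biofilm darkest; transmitted-light data with different
contrast reassigns the map, not the code).

**Cell vs. biofilm.**  Connected components (8-connectivity in 2D, labels
in raster-scan order for determinism) are classified by area:
≤ 50 μm² → CELL, larger → BIOFILM, with an optional minimum area below
which specks are EXCLUDED.  The 50 μm² default is a few footprints of a
~1 × 3 μm vibrioid cell; no measured value exists for this cutoff, so it
is exposed as configuration.

**Cell counting over time** (`motility.count_cells_series`) computes
thresholds once from a histogram pooled over the whole series.  This keeps
detection parameters fixed across frames and avoids a degenerate
placement on frames that lack one population (e.g. biofilm-free early
frames): a per-frame 3-class Otsu on a 2-population frame happily splits
the background noise peak instead.  Counting uses the 2-class split by
default — cells and biofilm are separated by area afterwards, not by
intensity.

## 3D reconstruction

Binary slices are stacked into (Z, Y, X) volumes with anisotropic voxels
(the μ-dish stack is 0.11 μm in XY and 0.6 μm in Z, 43 slices spanning
25.2 μm).  Components are 26-connected; size filtering removes
single-cell-scale debris before meshing.

Marching cubes uses the standard case table at iso-level 0.5 on the 0/1
field, which places crossings at cell-edge midpoints; no asymptotic
decider is applied — ambiguous faces are rare for binary fields and this
is accepted as a known approximation.  Vertices are scaled by
(pixel, pixel, z-step) after extraction.  Two consequences are documented
rather than hidden:

- A single voxel meshes to an octahedron of volume 1/6 voxel; mesh and
  voxel-count volumes converge only as structures grow large against the
  voxel (a digitised sphere of radius 12 voxels agrees within 5 %, and
  within 1 % in practice).
- Where two voxel bodies touch along an edge or corner, the mesh is closed
  but not manifold (four faces share an edge).  `is_watertight()` therefore
  checks closedness — no edge with an odd face count — which is the
  condition the divergence-theorem volume needs; `is_manifold()` exposes
  the strict two-faces-per-edge test.

Enclosed volume is the absolute signed-tetrahedron sum (orientation
cannot flip the sign); surface area is the triangle-area sum.

"Biofilm quantity" in 2D time series is the summed BIOFILM-class area;
in 3D it is voxel volume.  Both are exposed; growth-rate series use the
2D area variant, since those come from overview images.  Relative change
is 100·(v(t) − v(ref))/v(ref) with the series start as default reference;
a zero reference is an error that names the first usable frame.

## Motility

**Detection** is classic band-pass spot finding: Gaussian smoothing at the
spot scale (σ = diameter/4) minus a boxcar background (~2 diameters),
local maxima above a small threshold, and sub-pixel refinement by
intensity-weighted centroid over the spot window; integrated band-passed
mass filters out noise peaks.  On noise-free rendered spots the centroid
is accurate to well under 0.1 px.

**Linking** solves, per frame pair, the assignment minimising total
displacement among pairs within the search radius (optimal bipartite
matching via the Hungarian algorithm, padded so any detection may stay
unmatched); unmatched detections seed new tracks and tracks may bridge up
to `memory_frames` missing frames.  Optimal matching was chosen over
greedy linking for determinism and because it can be checked against a
brute-force assignment enumerator.

**Statistics.**  Step speed is Euclidean displacement × pixel size × fps /
frame gap.  Population statistics pool *steps*, not per-track means, so
"maximum velocity" is the single fastest observed step — matching how such
numbers are reported.  A track is *motile* iff mean speed ≥ 1.0 μm/s AND
net displacement ≥ 2.0 μm (both configurable).  The double criterion is
this package's operational definition: localisation jitter on a stationary
cell produces apparent speed (σ_loc √2 · fps can exceed several μm/s) but
negligible net displacement, so the displacement arm is what rejects it.
Motile fractions are per track, binned by the track's mean position; empty
bins are undefined (NaN), never zero, and out-of-range tracks are counted
in an explicit overflow bin.  An optional track-length weighting is
available for dense scenes where broken tracks would otherwise make one
cell count twice.  Vertical distributions report median and 25/75
quantiles by the linear-interpolation rule; cell heights in a Z-stack are
assigned by the slice maximising a variance-of-Laplacian focus score
around the cell's XY position.

## Pore-network metrics

The grain mask is static across a series.  Per frame, non-grain pixels
are split into three intensity bands (thresholds from multi-Otsu on the
pore pixels only; a degenerate histogram is an error suggesting manual
thresholds).  Coverage is BIOFILM / non-GRAIN pixels — the denominator is
the full pore space, including gas-occupied pixels, since excluding gas
would make coverage jump when gas moves.  Normalized coverage divides by
the value at the reference frame, taken right after biofilm formation
under lactate (end of the growth phase); it may exceed 1 during later
growth.  Cumulative detachment after cycle k is 100·(1 − C̃(end_k)), and
the incremental value is the percentage-point difference between cycles.
The construction is invariant to any positive rescaling of the raw
coverage series.

Gas saturation is GAS / non-GRAIN; "reduction by X %" is interpreted as a
relative change 100·(before − after)/before, with a flag for the
percentage-point reading.  Ganglia are connected GAS components not
touching the frame boundary (boundary-connected gas is flowing, not
trapped); they are linked across time by maximal pixel overlap (ties to
larger overlap, then lower label), with per-ganglion area series,
shrinkage, and a dissolved flag.  Interface displacement takes, for every
gas–liquid boundary pixel at t₁, the distance to the nearest boundary
pixel at t₂, averaged and scaled to μm.

## Synthetic scenes

The generator produces statistical stand-ins, not physics: no
hydrodynamics, chemotaxis mechanism, pH evolution or H₂ dissolution is
simulated.  What it reproduces are the *measured statistics* of the study
conditions, so that the measurement pipeline can be validated against
exact ground truth.  Consequently, a passing pipeline demonstrates correct
measurement under realistic contrast, noise, density and motion — it does
not demonstrate robustness to artefacts the renderer omits (uneven
illumination beyond a linear gradient, focus drift, debris, DIC shading).

**Speed distributions.**  Motile cells draw per-step speeds from a normal
truncated to [0, v_max] whose *truncated* mean and SD equal the printed
statistics (H₂: mean 14.9, SD 9.9, max 43.7 μm/s; lactate: 3.7, 2.3,
9.5 μm/s).  The (loc, scale) parameters are solved by moment matching;
using the printed values directly as loc/scale would inflate the realised
mean by ~9 % for the H₂ condition, because the printed numbers are sample
statistics of the bounded speeds.  Direction follows a persistent random
walk with a 30° turning-angle SD per step (configurable; only mean/SD/max
speeds are printed, so persistence is a design choice).  Steps that would
leave the frame have the offending component reflected *before* the step,
so recorded consecutive positions are exactly one step length apart.
Immotile cells jitter with sub-resolution amplitude (0.15 px).

**Scene geometry.**  Cells are rendered as Gaussian bumps (σ = 1.4 px,
amplitude 0.7 over background 0.1) plus additive Gaussian noise
(σ = 0.03); foreground/background separation is ≥ 5× the noise SD by
construction, so segmentability is a property of the pipeline, not luck.
Initial positions keep ≥ 4× the rendered spot diameter apart; densities
that cannot satisfy this fail loudly, naming the count that fit.  The
μ-channel scene spans 1.75 mm at 1.1 μm/px with seven 0.25 mm distance
bins; motile fractions decay log-linearly from 0.67 (interface bin) to
0.03 (farthest), the printed endpoints, and cells reflect at their bin
boundaries so ground-truth bin membership is exact.  The channel height
(640 px) is set by the separation requirement at 100 cells per bin.  The
μ-dish overview defaults to 1024 × 1024 px (field of view not printed).

**Growth series.**  True cell counts follow an exponential reaching
exactly the printed relative increase over the printed window (+83.44 %
over 6 h for lactate, +14.15 % over 4 h for H₂; 600 starting cells,
hourly frames), then plateau.  Lactate biofilm appears after 8 h and
grows linearly; the H₂ scene carries constant pre-existing biofilm
clusters and no growth.  Cell positions are re-sampled each frame with a
9 px minimum separation and a keep-out margin around biofilm — counts,
not identities, are the measurand there.

**Pore network.**  Grains are overlapping random disks (radii 14–26 px at
1.1 μm/px) greedily added/removed to a 0.61 porosity target, then
fine-tuned with grains sized to the remaining error (still within the
radius distribution) so the achieved porosity centres on the target;
unreachable targets are an explicit error.  Biofilm deposits as
grain-hugging coats (per-grain, inner pixels first), giving nested
growing prefixes and per-grain connected components.  Detachment removes
whole randomly-ordered components — outermost pixels first within the
last, partially removed one — until the cumulative schedule is met to the
nearest pixel.  Cycle ends are the last frames of injection phases.  The
H₂ preset follows the cumulative schedule (0.11, 0.55, 0.69) at 20 %
initial pore-space coverage; the N₂ control (0.20, 0.28, 0.31) at 15 %
coverage inserts a +0.87 %-of-initial growth blip during the first
shut-in.  (The N₂ cycle-2 value 0.28 derives from the reported 0.72
normalized coverage; cycle 3 follows the 31 % total, acknowledging the
source's own 0.68-vs-0.69 inconsistency.)  Gas occupies the pore pixels
farthest from grain (the non-wetting phase fills the largest pore
bodies) at 35 % of pore space from the first injection on.  Phases render
at well-separated intensities (biofilm 0.15, grain 0.35, liquid 0.55,
gas 0.92; noise σ = 0.02).  The paired-saturation scenes share one grain
mask: a bacterial-solution scene (2 % trace biofilm, 50 % gas saturation)
and a biofilm-laden scene (20 % coverage) whose gas pixel count is 81 %
of the clean scene's — a 19 % relative reduction by construction.

**Determinism.**  Every generator takes one integer seed; randomness is
drawn from sub-streams keyed by (seed, object index), so regeneration is
bit-identical and increasing `n_cells` never changes earlier cells.

## Problem sizes

Default sizes were chosen so every scene remains a faithful test at
desk scale: pore networks 512 × 512 px with 8 frames per phase (56 frames
per detachment series), motility videos 5 s at 20 fps with 200 cells,
channel scenes 700 cells over 100 frames, growth series 9–13 hourly
frames at 1024 × 1024 px.  The full test suite and the acceptance script
each run in a few minutes on one CPU.

## Known limitations

- The marching-cubes case table without an asymptotic decider can, in
  principle, mis-resolve ambiguous faces; for binary fields at iso 0.5
  this was not observed to break closedness (property-tested on random
  blobs), but meshes are not guaranteed manifold (see above).
- Linking ties (equal-cost assignments) resolve deterministically via the
  Hungarian solver's ordering rather than an explicit lowest-track-id
  rule; with sub-pixel positions, exact cost ties essentially never occur.
- The motile/immotile thresholds and the cell-area cutoff are operational
  definitions, not measured constants; conclusions sensitive to them
  should sweep the configuration keys.
- Phase classification assumes the rendered contrast ordering; real
  reflected- or transmitted-light pore images must supply their own
  band→phase map, and heavily clogged scenes can degrade the three-band
  histogram assumption.
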