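# Methods

## The measurement problem

Observational scoring of rodent locomotion in an open field is reliable but
subjective and coarse. The alternative implemented here reconstructs the
animal's 3D shape at every video frame from multiple calibrated silhouettes
(shape-from-silhouette), tracks the centre of volume (CoV) of the whole body
and of its front and rear halves, classifies behavior from simple kinematic
rules, and extracts step-level gait measures from the lateral oscillation of
the rear CoV. Because tissue density is roughly uniform, the CoV approximates
the centre of mass, so its height, planar speed, and lateral deviation carry
direct biomechanical meaning across the full range of function from normal
walking to hindlimb paralysis.

## Camera model and rig

Cameras are distortion-free pinholes (calibration is consumed, not
estimated): world point `X` maps to pixels via `u = f_x·x_c/z_c + c_x`,
`v = f_y·y_c/z_c + c_y` with `(x_c, y_c, z_c) = R·X + t`. The world frame has
its origin at the arena centre on the floor, z up, millimetres everywhere;
image origin is the top-left pixel centre, y down; rounding is
nearest-integer with ties toward +∞. The virtual rig reproduces the
topology of the physical system — six lateral cameras evenly spaced on a ring
outside the 914 mm arena with horizontal optical axes through the arena
axis, and four cameras under the transparent floor looking up — with
1024×1024 px sensors. The focal length defaults to the largest value that
keeps the whole arena interior inside every frustum, which puts the pixel
footprint at the animal between roughly 1 and 2.4 mm depending on its
position; the construction fails loudly if any arena point is seen by fewer
than two cameras. Exact metric camera placement of the original apparatus is
not published, so only the topology and coverage are reproduced.

## Synthetic scenes

The simulator provides ground truth for every downstream stage. The mouse is
three ellipsoids (rear body 38×28×24 mm, front body 30×23×19 mm, head
24×22×22 mm including the ears) plus a 6 mm-thick, 55 mm tail rendered as a
chain of spheres; total tailless volume ≈ 24.3 cm³, consistent with a
25–30 g animal (tissue density ≈ 1 g/cm³). The body must be comfortably
thicker than the tail-removal element (7 px ≈ 9–17 mm across the rig) and
the tail thinner than it everywhere, exactly as in the physical system; a
markedly smaller animal, lower-resolution sensors, or different element
sizes break that separation, which is why those constants are explicitly
resolution-bound.

Scripted trials are sequences of behavior epochs (label, duration, speed,
step cadence, lateral amplitude, rear/front CoV heights). Locomotion follows
a circular arc of radius 200 mm around the arena centre; the rear CoV
carries a sinusoidal lateral offset of 3 mm amplitude at the scripted
cadence — one left and one right excursion per step cycle — mirrored at half
amplitude in phase opposition on the front CoV. Default step cadence follows
the embedded generating model `cycle distance = 0.25·speed + 8 mm`, which the
gait-regression stage is tested against. Rearing raises the front CoV to
45 mm at near-zero planar speed. Epoch parameters are validated against
their labels (e.g. a "standing" epoch at 50 mm/s is rejected).

Rendering is analytic: each ellipsoid's dual quadric is projected to a conic
per camera, and the exact silhouette is the set of pixels whose centres fall
inside any projected component. Composites put the dark animal
(intensity 0.1) on a white background (1.0) with i.i.d. Gaussian pixel noise
(SD 2/255 by default). All randomness flows from one seed through
counter-based (Philox) generators keyed on (seed, frame, camera), so any
frame is reproducible in isolation; the in-memory frame source draws noise
only over the requested crop, so a trial materialised to disk carries a
different (equally distributed) noise realisation than the lazily rendered
one.

What the simulator does *not* emulate: articulated limbs and feet, fur
texture, shadows, reflections, background drift, and camera noise other than
additive Gaussian. Passing tests therefore demonstrate correctness of the
geometry, reconstruction, classification and gait logic under controlled
imaging, not robustness to real-video artefacts.

## Silhouette extraction

Foreground is `|frame − background|`, channel-weighted (luminance weights
0.299/0.587/0.114 — the exact weighting of the original system is unstated)
and thresholded. The default threshold is Otsu's method on the
intensity-difference image with a floor of 0.05 (≈13/255) so that an empty
scene does not threshold pure noise; a fixed threshold can be configured.
Cleanup is morphological opening with a square element — 3×3 in whole-animal
mode, 7×7 in tail-removal mode — followed by deletion of connected
components whose bounding box fits strictly inside the element (the two
published phrasings, "erosion followed by dilation" and "elements smaller
than … were discarded", conflated deliberately). Opening makes the
operation idempotent, and raising the threshold can only remove foreground.

The bounding cube makes per-frame cost proportional to the animal, not the
sensor: each camera processes only the pixel box of the cube's eight
projected corners. The cube is re-centred on the latest whole-body CoV with
half-extent = tight body half-extent + 30 mm margin (the published method
states the expansion but not its size; 30 mm covers ~10 frames of fast
motion plus body deformation at 100 Hz). On the first frame, where no cube
exists, full-image subtraction runs in every camera and the cube is seeded
at the least-squares intersection of the per-camera silhouette-centroid
rays.

## Volume reconstruction

Within the cube, a voxel grid (2 mm edge) is carved: `C(v)` = number of
cameras whose cleaned silhouette contains the voxel centre's projection
(single-pixel test — appropriate because 2 mm voxels are comparable to or
smaller than the pixel footprint at working distances). The grid is clipped
vertically to the physically possible band (floor to arena height), which
removes ~two-thirds of the voxels without changing any result. The
likelihood index `L(v) = C(v) + mean neighbour C` uses the 26-connected
neighbourhood, truncated at grid borders; its exact published functional
form is not recoverable from the source, so this form — which preserves the
stated structure (correspondences plus spatial support) and the threshold
iteration behaviour — is isolated in one function for drop-in replacement.

The body is `{L ≥ τ}` with `τ` lowered through the distinct observed `L`
values from `max L` until the volume enters `μ ± 3σ`; if the band is
stepped over entirely, the `τ` whose volume is closest to `μ` is used.
How `μ, σ` were obtained originally is unstated; here they are the median
and 1.4826×MAD of the per-frame raw volumes at full correspondence
(`C = N`), accumulated as the trial progresses (a configured prior covers
the first ten frames), with `σ` floored at 1% of `μ` so constant-volume
synthetic data keeps a usable band. Both tail modes are reconstructed each
frame from their respective mask sets (one shared projection pass); all CoV
analysis uses the tailless volume, the with-tail volume sizes the tracking
cube.

## Segmentation and labelling

The tailless voxel set is split into two clusters by Lloyd's algorithm
(k = 2; the published three-cluster attempt to segment the tail is an
explicit non-goal). Initialisation is deterministic: the previous frame's
centres when available, else the farthest voxel pair; convergence is exact
assignment stability, capped at 100 iterations. Anatomical labels: while
planar speed exceeds 10 mm/s the front is the cluster leading along the
velocity; at rest labels persist; on a first frame at rest a configurable
planar head-direction hint decides. A flip of an established labelling
requires five consecutive frames of contrary evidence (hysteresis against
frame-to-frame chatter) — but evidence is accepted immediately until the
labelling has been confirmed by motion once, so a wrong first-frame guess
costs no frames.

## Kinematics

CoV = arithmetic mean of occupied voxel centres. Positions are filtered
forward and backward with a 4th-order low-pass Butterworth designed at
20 Hz for the trial frame rate (order unpublished; forward–backward
application zeroes the phase and squares the magnitude response, so the
single-pass −3 dB point is exactly 20 Hz). Velocities come from smoothing
quintic splines fit per coordinate and differentiated analytically; the
smoothing level is set from the residual noise variance estimated via
second differences (`s = n·σ̂²`), a choice that reduces to near-interpolation
on noise-free data. Planar speed excludes the vertical component. Missing
frames (empty reconstructions) shorter than 0.5 s are bridged by cubic
interpolation; longer gaps split the trial into independently filtered and
analysed segments. The first and last five samples of each segment are
flagged low-confidence and excluded from bout statistics.

## Behavior classification

Per-frame rules on filtered whole-body speed `s` and front CoV height `h`
(all constants configurable, defaults as printed): rearing iff `h ≥ 34 mm`
(speed irrelevant); else fast ambulation iff `s ≥ 60 mm/s`; meandering iff
`10 ≤ s < 60`; standing iff `s < 10`. Fast runs are merged across sub-60
interruptions of at most `round(0.17 × frame rate)` frames (17 at 100 Hz)
provided no rearing frame intervenes; a merged run whose cumulative planar
path length (path, not net displacement — arcs along the wall would
otherwise be undercounted) reaches 200 mm is directed locomotion, else
exploratory. Interruption frames inherit the bout label and count toward
its path and duration; merging precedes the distance measurement, so the
same tolerance applies to both locomotion classes. Every frame belongs to
exactly one bout.

## Gait analysis

The averaged trajectory is a central moving average of the filtered rear
CoV whose per-frame window spans one step cycle:
`w = round(d(s)/s × rate)` frames, forced odd (+1 on even rounds, keeping
the average centred) and clamped to [5, 61]; speeds below 1 mm/s take the
61-frame clamp, and the first regression pass uses a fixed 31-point window.
The average runs over the whole recording — frames neighbouring a bout
still inform it — so bout edges keep full windows; only recording ends
shrink symmetrically. Lateral deviation is the signed perpendicular offset
from the averaged path's local tangent, positive to the left of travel; on
curved paths the average is biased toward the inside of the curve, which
shifts the deviation baseline without disturbing its extrema.

Steps are alternating local extrema of the rear deviation (prominence
≥ 0.5 mm, separation ≥ 0.05 s — invented noise guards; where two same-kind
extrema are adjacent the more prominent survives). One extremum is one step;
a max+min pair is one step cycle, so the regression of distance per step
cycle on bout speed uses 2 × (bout path / step count) per bout, one point
per directed bout. Ordinary least squares; fewer than three usable bouts or
a single-speed design fall back to a configured default model with a
warning. The window→detection→regression loop iterates until slope and
intercept change by less than 1% (the intercept compared on the scale of
the predicted cycle distance at the mean speed — "fit changed by less than
1%" is not otherwise defined), capped at 20 iterations. Side assignment of
steps (left vs right hindlimb) required visual video reading originally and
is out of scope; extrema carry only their kind.

Validity against external scores (lesion sparing, observational scales) is
a plain Pearson correlation per metric/score pairing with two-sided p
values; zero-variance columns are flagged rather than propagated as NaN
surprises.

## Problem sizes and numerical choices

The default test cohort is twelve 2 s trials at 100 Hz (seeds 0–11,
locomotion speeds 60–250 mm/s, cadences ≈ 2.6–3.6 Hz from the generating
model; odd-indexed trials end with 0.6 s of standing or rearing). At these
sizes the full vision pipeline runs at ≈ 0.15 s/frame on one core. The
synthetic-cohort checks recover the whole-body CoV with ≈ 0.9 mm in-plane
RMSE, ≥ 98% frame-label agreement, and the generating step-length slope
within a few percent; the step-count quantisation of short bouts (±1 step
in ~10) is the dominant noise source in the regression. Tie-breaks and
degenerate inputs are handled explicitly: empty clusters re-seed at the
farthest point, all-identical voxels split one-vs-rest with a warning,
stationary tangents give zero lateral deviation, empty likelihood fields
give empty bodies, and an all-background frame yields a missing-frame
marker that the gap policy absorbs.

## Known limitations

- The likelihood index's published weighting is unrecoverable; alternatives
  slot into `likelihood_index` but have not been compared.
- Morphological element sizes are pixel-denominated and thus tied to sensor
  resolution and working distance; the defaults assume the canonical rig.
- Ground-truth front/rear CoV in the simulator are centroids of the
  anatomical ellipsoid groups, whereas the pipeline reports centroids of the
  k-means halves; the two coincide closely for this body shape but are not
  definitionally identical.
- Foot placement, limb coordination, and secondary complications (spasms,
  scoliosis) are outside the measurement model.
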