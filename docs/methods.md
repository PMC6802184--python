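# Methods

This note records the models, conventions and numerical choices behind
`innerstate`, in the spirit of a model-documentation page: what each stage
assumes, which knobs matter, and what the synthetic validation does and does
not establish.

## Input model

The pipeline's universal input is a binary neurons-by-time matrix. For
imaging-like data each accepted Ca²⁺ event marks the neuron active for two
consecutive frames at the transient peak; for spike data, activity is binned
at 100 ms and binarized. Frame-level activity vectors pass a modality filter
(>1 active neuron for imaging, ≥15 for electrophysiology) before any
analysis; original bin indices are preserved so behavior stays aligned for
validation.

### Ca²⁺ event detection

Per neuron: subtract the sliding-window median (20 s), low-pass at 2 Hz
(zero-phase second-order Butterworth — only the cutoff is conventionally
fixed, so we choose a standard zero-phase design), threshold at k·MAD of
the filtered trace (k = 4 for GCaMP6s, 5 for GCaMP6f; the MAD is computed
globally over the session for determinism), require an indicator decay time
of ≥600/200 ms measured from the peak to the first crossing of half the
peak amplitude (the criterion names a decay time but not its measurement;
half-amplitude is the standard choice), and apply within-candidate-event
prominence rules (a later peak must rise k MAD above the previous peak and
k/2 MAD above the next to count separately). Neurons below 0.01 Hz event
rate or 1% mean ΔF/F₀ amplitude are discarded. Neighbor crosstalk handling
(<18 µm pairs) accepts a pair list as input, since footprint extraction is
out of scope. False-positive rates scale with record length: low-pass
filtered noise has exactly the transient timescale, so the decay criterion
does not veto noise bumps and only the amplitude threshold does.

## Two-stage spectral embedding

Both stages solve the generalized eigenproblem L f = λ D f on an
OR-symmetrized, binary-weighted kNN graph and keep the eigenvectors after
the leading constant one. Defaults: p₁ = 0.375% (midpoint of the 0.25–0.5%
working range) with 10 output dimensions, then p₂ = 11.25% (midpoint of
7.5–15%) with 3 output dimensions. Distances are Euclidean — the natural
default, monotone in Hamming distance for binary vectors. kNN ties break
at the lowest frame index (chunked brute-force search with a stable sort,
so this holds at every problem size). Numerically the problem is solved
through the normalized adjacency D^{-1/2} W D^{-1/2}: its largest
eigenpairs are the smallest generalized ones (λ = 1 − µ). Graphs with up
to 1500 nodes use a dense symmetric eigensolver because a Lanczos iteration
started from a single vector cannot split the exactly degenerate eigenpairs
of symmetric graphs (e.g. the paired harmonics of a ring); larger graphs
use ARPACK with a deterministic seeded start vector, tolerance 1e-10, and a
small over-request so near-degenerate multiplets resolve. Signs are
canonicalized (largest-magnitude entry positive). Disconnected graphs are
restricted to their largest component with the dropped frames reported —
components are never silently mixed.

Track sessions in the bundled studies use p₂ = 7.5% (bottom of the range)
because their state clusters hold only one to two thousand frames and a
denser graph would force-merge small states into large ones. For
sub-embeddings of single running states (~3k frames) the relevant quantity
is the stage-1 neighbor *count*, not the fraction: the working fractions
give each node ~30–90 neighbors at full-session scale, so
`linear_reconstruction` floors the count at 30 (exceeding the nominal
fraction range for small sub-populations). With only ~10 neighbors per
node the sub-embedding geometry is seed-fragile — folded or compressed
coordinates, fragmented landmark topology.

## Geometry and topology

**Intrinsic dimension.** The mean cumulative neighbor count within radius r
grows as r^d on a d-manifold. We average counts over up to 2000 reference
points on a data-derived geometric radius grid (scale-invariant by
construction). The slope is read from the most linear window of 10
consecutive log-log grid points, with candidates restricted to mean counts
in [10, 0.5·n]. A fixed count window cannot work here: for a 1-d manifold
with ~10% relative transverse noise the crossover from the noise-thickness
regime (local slope ≈ 2–3) to the manifold regime extends past 10% of n,
so the scaling regime must be located from the curve itself — as one does
by eye when fitting the straight region of such plots.

**Betti numbers.** Vietoris–Rips persistence up to homology dimension 2 on
landmark points: centroids of a seeded K-means (K = 70, 10 restarts, best
inertia) after discarding clusters with fewer than 50 members; fewer than
50 surviving landmarks flags the result low-confidence. The persistence
computation is implemented in-package: dimension 0 by a union-find sweep;
dimensions 1–2 by GF(2) boundary-matrix reduction with columns as integer
bitmasks, using the apparent-pairs shortcut (a simplex pair where each is
the other's youngest facet / oldest cofacet is a zero-persistence pair and
needs no reduction) and clearing (triangles paired during the tetrahedron
reduction are known cycle-creators and are skipped in the triangle
reduction). The maximum filtration radius defaults to the 99th percentile
of pairwise landmark distances. A Betti vector counts as stable when it
persists over ≥25% of [0, r_max]; the widest plateau wins. The whole
computation is validated against an exhaustive GF(2)-rank oracle in the
test suite.

## Network states

**Topological clustering.** Single-linkage component structure comes from
an MST built on a kNN graph (bridged between components when needed) —
exact whenever that graph is connected. The radius is chosen to capture
the maximal number of stable components with ≥250 members (≥50 for
sub-clustering): component counts are scanned on a geometric radius grid,
a count is stable when it persists over ≥5% of the log-radius range, and
multi-cluster plateaus must additionally not grow their total membership by
more than a factor of two across the plateau. The log-scale grid matters —
a few outlying MST edges otherwise stretch a linear radius range until the
all-merged regime dominates every plateau comparison. The membership gate
separates genuine dense clusters from diffuse clouds whose single "cluster"
keeps swallowing points; it deliberately exempts single-component plateaus,
because one dense blob legitimately absorbs everything (and a shuffled
session, whose embedding is exactly such a blob, is then recognizable by
having at most one, trivial, whole-cloud state rather than a discrete state
set). Unassigned points join the cluster of their nearest assigned
neighbor. Continuously distributed data (the ring; the within-state running
continuum) is parameterized with seeded K-means instead (K = 8 for the ring
by convention, K = 10 for running sub-states), since a continuum has no
stable discrete components to find.

**Segmentation.** Per state independently: runs of member frames with
internal gaps ≤ max_gap are merged; candidate segments with fewer than
min_length member points are dropped. max_gap defaults to the smallest
value at which the total segment count changes by <5% under a ±1
perturbation (robustness criterion); min_length to the antimode of the
member-count distribution, estimated by the valley of a log-scale kernel
density between its two dominant modes (the distribution is bimodal:
genuine visits hold many points, noise excursions few). Member counts, not
temporal spans, feed the antimode — gap-merging inflates the spans of noise
segments but not their membership.

**Subtypes.** Segments of one state are summarized by their mean activity
vectors and projected on their first principal component; two subtypes are
declared iff the projection histogram shows two modes separated by at least
one empty bin, with each mode holding ≥2 segments and ≥10% of them. The
bin count is the Freedman–Diaconis choice floored at 10 bins:
Freedman–Diaconis under-bins exactly in the strongly bimodal case this test
exists to detect (the IQR then spans both modes), and the per-side
population guard prevents a lone outlier segment from counting as a
"separate cluster".

**Ordering.** The ordering maximizes the summed transition probability
between consecutive states, exhaustively. Linear mode fixes the first and
last states as those most frequent at the beginning and end of each visit
(traversal) and searches the (M−2)! interior permutations; cyclic mode
searches the (M−1)!/2 rotation/reflection-distinct orders of the
both-neighbor objective. M > 10 is rejected (factorial search) with
guidance to coarsen the clustering. Within-state sub-clusters are ordered
on frame-level transitions: consecutive data points sample fast-crossed
mid-track sub-states well, while segment-level successions under-sample
them. Ties resolve to the lexicographically smallest permutation.

## Internal variables and tuning curves

Ordered sub-cluster k of M gets internal position k/(M−1); ring cluster k
gets angle 2πk/M, then temporal smoothing with a truncated Gaussian (σ = 2
frames, 5-frame support) applied to the unit vectors (cos, sin) to avoid
wrap artifacts. The linear case is left unsmoothed. Gauge freedom —
reflection for a line, rotation (searched on the state/bin grid) times
reflection for a ring — is fixed by minimizing the global mean squared
error against the external variable, and only when such a comparison is
requested; circular mismatches use mod(θ̂ − θ + π, 2π) − π.

Internal curves: occupancy and event counts per ordered state, linearly
interpolated onto the spatial-bin grid (20 bins), both maps smoothed with a
truncated Gaussian (σ = 1.5 bins, 5-bin support), then divided. Circular
curves use 40 bins of 9° with no interpolation or smoothing. Neurons need
>5 events within the covered states. External positional curves: 24 4-cm
bins with the outer 2 bins per end excluded, frames restricted to speed
>1 cm/s, per running direction (trajectory-phase curves pool directions
after flipping one side's indexing); angular curves use the 40-bin
convention.

Information per event uses the unsmoothed maps. Its shuffle null redraws
each event's bin i.i.d. from the occupancy distribution — the natural
reading of "shuffles accounting for coverage statistics" — and a cell is
significant iff its information strictly exceeds 95% of its shuffles.
Leave-one-out internal information excludes the cell, re-embeds the rest,
clusters into 8 K-means states (matching the 8 external bins of the
comparison) and subtracts the mean of 100 time-shuffles of the held-out
cell, removing the occupancy-statistics bias.

## Decoders

The maximum-likelihood decoder assumes independent Poisson events given the
binned rates, with a rate floor of 1e-3 events/s (the method is named
"maximum likelihood" without a noise model; Poisson is the standard for
binned events). Across-session decoding matches each test frame's internal
coordinate to the reference state with the nearest internal coordinate
under the best symmetry element (reflection for a line; grid rotations ×
reflection for a ring), decoded as that state's associated external value;
the symmetry is fixed by minimizing decoding MSE, mirroring the gauge
convention of the shuffle test. The trajectory-phase decoder returns the
training phase of the nearest embedded neighbor from the opposite running
direction (ties to the earliest frame). Template decoders average training
activity per bin (20 bins of phase, time-in-traversal, or
speed-by-acceleration: 10 bins 0→40 cm/s speeding up then 10 slowing down)
on even minutes, decode odd-minute frames by maximal Pearson correlation on
raw binary frames, and report explained variance
1 − MSE(data)/MSE(label shuffle preserving label probabilities). The
decoding shuffle test permutes decoded values across time bins and re-fits
the gauge per shuffle; p = (1 + #{null ≤ observed})/(n_shuffles + 1),
1000 shuffles by default. The phase/time variability maps (20×20) weight
the within-slice standard deviations by occupancy so thinly sampled bins,
whose rate estimates are noise-dominated, do not drive the SD_P vs SD_T
comparison.

## Synthetic sessions

The generators emulate the recording conditions the pipeline targets, not
attractor dynamics — tuning is imposed, not emergent.

* **Track behavior**: alternating traversals of a 96-cm track with
  drinking (2–4 s) and turning (1.5–2.5 s) pauses at both ends, occasional
  rearing (p = 0.15 per turn), and a trapezoidal speed profile cruising
  near 40 cm/s (ramps at 30 cm/s²) with trial-to-trial peak-speed jitter of
  6 cm/s. The jitter matters: it decorrelates time-in-traversal from
  trajectory phase enough that phase-coding and time-coding cells are
  distinguishable, as they are in real, variable behavior.
* **Populations**: CA1-like sessions plant 60% direction-selective place
  cells (Gaussian fields, σ = 6 cm, peak 0.8–2 events/s, 30% rate in the
  non-preferred direction), 15% drink and 15% turn cells tied to one end
  (peak 1.5–3 events/s), 10% untuned; ACC-like sessions plant 50%
  trajectory-phase cells plus drink/turn/rear cells responding identically
  at both ends. Events are Bernoulli per frame with probability rate·Δt,
  matching the binarized raster downstream; rates were chosen so retained
  frames carry a realistic 2–4 active cells out of 400 and each behavioral
  state's ensemble is as distinguishable as in real recordings.
* **Head direction**: von-Mises tuning (κ = 3, peaks 10–40 Hz, baselines
  0.5–1.5 Hz), heading a bounded-speed random walk (OU angular velocity,
  SD 1.25 rad/s, τ = 1 s, clipped at 3 rad/s); REM episodes drive the same
  cells with the same walk at twice the speed — the factor is a free
  default, as no quantitative REM heading-speed statistics exist to pin it.
  The behavior track stores the virtual REM sweep in ``head_direction``,
  since it is the planted oracle for sleep decoding.
* **Fluorescence**: rise-plus-exponential-decay kernels (decay 600 ms
  GCaMP6s / 200 ms GCaMP6f), log-normally jittered amplitudes around 0.1
  ΔF/F₀, slow Gaussian-filtered baseline drift and white noise.
* **Multiday sessions**: neurons participate independently per day with
  probability s = 2·overlap/(1 + overlap), giving the requested expected
  Jaccard roster overlap (default 0.525, the midpoint of the 41–64% range
  observed across days in comparable recordings); retained neurons keep
  their tuning exactly.

All randomness flows from one session seed through
`numpy.random.SeedSequence.spawn`.

What the synthetic data does **not** contain: emergent attractor dynamics,
theta-scale temporal structure, slow representational drift within a
session, behavior-dependent rate remapping, or realistic imaging artifacts
beyond drift and white noise. Passing the validation suite therefore shows
that the pipeline recovers planted structure under realistic sparseness,
noise and session statistics — not that it would survive every pathology of
real recordings.

## Problem sizes of the bundled studies

The validation studies and the reproduction script run linear-track
sessions of 400 neurons × 21 min (seven 3-min trials; the experiments they
emulate used 450–600 neurons over five to seven trials) and head-direction
sessions of 50 cells × 30 min at 100-ms bins. The leave-one-out
information study uses a compact, denser session (120 neurons, 15 min at
10 Hz, elevated rates) because it re-embeds the population once per held-out
cell. These sizes are the package's own choice of a representative regime;
all stages accept larger inputs unchanged.

## Known limitations

* The factorial ordering search caps the number of orderable states at 10;
  finer parameterizations need coarser clustering or fewer sub-states.
* Evenly spaced internal positions assume the ordered sub-states tile the
  encoded variable roughly uniformly; strongly non-uniform occupancy (e.g.
  purely triangular speed profiles) distorts the reconstruction.
* The membership-stability rule distinguishes discrete state sets from
  diffuse clouds, but a single dense blob and a shuffled session are
  topologically identical at the cluster level — both yield one trivial
  state, and only the multi-state structure is diagnostic.
* Persistence runs on ≤70 landmarks; sub-landmark-scale topological
  features are invisible by construction.

Addendum — landmark threshold at sub-embedding scale: the 50-point
sparse-cluster discard assumes full-session clouds (mean K-means cluster
membership 140-350 at K = 70). Running-state sub-embeddings hold ~3k
frames, where the same cutoff discards most landmarks and fragments the
component count; the bundled running-state topology study therefore scales
the discard threshold to about half the mean cluster membership
(``max(10, n // 200)``), preserving the cutoff's role — rejecting
noise-dominated clusters — at the smaller scale. Head-direction sessions
keep the exact K = 70 / 50-point convention.

Addendum — variability across generator seeds: shuffled controls embed to a
structureless cloud, but at some seeds a few small density lumps in that
cloud pass the 250-point component floor, so the clustering may report one
dominant whole-cloud component plus satellites rather than a single trivial
state. The diagnostic contrast survives: shuffled sessions never reproduce
a set of comparable dense states, whereas genuine sessions consistently
yield the five behavioral-state clusters. Similarly, the running-state
sub-embedding's dimension slope concentrates near 1 but can reach ~1.4 at
unlucky seeds when the embedded curve folds locally.
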