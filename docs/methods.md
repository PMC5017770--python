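# Methods

This note documents the models, algorithms and numerical choices behind
`radarperm`: what is computed, under which assumptions, and what the
synthetic tests do and do not demonstrate about measured data.

## Imaging model

A monostatic scan is a set of time-domain reflection traces, one per
antenna position, on a common time axis.  The target is modelled as a
centred layered phantom: a thin skin shell (thickness t, default 2 mm,
permittivity ε_s) around a homogeneous interior (permittivity ε_i) of
outer radius R.  All tissues are treated as lossless and non-dispersive,
so a single real permittivity per layer fixes the signal speed c/√ε.

The round-trip delay from an antenna at **a** to an interior point **p**
is computed along the straight ray, partitioned by region:

τ(**a**, **p**) = 2 (L_out + √ε_s · L_skin + √ε_i · L_int) / c,

with L_out, L_skin, L_int the ray lengths outside the phantom, in the
shell and in the interior.  Refraction at the layer boundaries is
ignored, consistent with treating each layer as a bulk effective medium.

Delay-and-sum (DAS) reconstruction assigns to each pixel the sum over
antennas of the trace amplitude at τ, with linear temporal interpolation
for sub-sample delays and zero contribution beyond the trace end.  No
per-channel weighting or attenuation compensation is applied — the
estimator only needs relative image quality, and plain coherent summation
keeps the model minimal (weighting is an obvious extension point).
Pixels outside the reconstruction region (the interior of the known skin
contour) are exactly zero.  Pixel indices map to physical centres as
origin + (index + 0.5)·spacing; the default grid uses 1 mm pixels.
Signed amplitudes are kept through reconstruction; absolute values are
taken only by the fitness, since a coherent *negative* response can be
the more faithful rendering of a scatterer.

### Calibration and skin suppression

Empty-scanner reflections are removed by subtracting a calibration scan
recorded with identical antenna positions and no target.  The dominant
skin reflection is then suppressed per trace: the primary reflection
window is detected as the contiguous span where the smoothed rectified
envelope exceeds 10 % of its maximum (padded by 25 samples so the pulse
tails are covered); the k = 4 most similar traces inside that window (RMS
difference) are averaged, scaled by least squares, and subtracted, with a
cosine roll-off confined to the padded margins.  Samples after the window
— in particular tumour echoes — are untouched.  This is a deliberately
simplified neighbourhood filter: it exploits the fact that the skin
response varies slowly from one antenna position to the next while
scatterer responses do not.  Like any such filter it degrades responses
that overlap the skin window (scatterers close to the skin) and removes
large, antenna-invariant structures such as a centred gland.

## Image fitness

A good DAS image has one bright, compact response and a quiet background.
The score is

f₁ = S_max / (N · A),    f = f₁ · P,    P = min((d / 3 mm)³, 1),

- S_max — maximum of |image| over the masked region;
- A — area (mm²; volume in mm³ for 3D grids) where |pixel| > S_max/2,
  using a *strict* inequality so exact half-peak ties are excluded;
- N — number of connected components among those pixels, 8-connected in
  2D and 26-connected in 3D, so diagonal blobs count as the single
  response a human reader would see;
- d — Euclidean distance from the peak pixel centre to the boundary of
  the masked reconstruction region (falling back to the array edge when
  no mask is present).  The 3 mm penalty scale covers a typical 2 mm
  skin thickness plus a 1 mm buffer, vetoing the bright edge artifacts
  that some permittivity choices produce.

An all-zero image is defined to score f = 0 (degenerate flag) to avoid
0/0.  Measuring A in physical units rather than pixels only rescales f
globally and cannot move its argmax.

## Sparse-grid surrogate of the fitness surface

Each fitness evaluation costs a DAS reconstruction, so the surface over
the search box is sampled parsimoniously.  The box (default ε_i ∈ [1, 12],
ε_s ∈ [2, 70], covering the plausible tissue range at microwave
frequencies) is mapped affinely onto the unit square with coordinates
ζ = (ζ₁, ζ₂).

Nodes live on nested equidistant (Newton–Cotes) 1D families: level 0 is
the midpoint 0.5, level 1 adds the endpoints {0, 1}, and level i ≥ 2 adds
the 2^(i−1) new dyadic midpoints.  The d-dimensional level-L grid is the
Smolyak union over level sums ≤ L; in 2D the cumulative counts are 1, 5,
13, …, 321 (level 6), …, 7169 (level 10).  Interpolation uses
hierarchical piecewise-multilinear hat functions (support 2^−(i−1) at 1D
level i; the level-0 basis is the constant 1).  Each node carries a
hierarchical surplus — sampled value minus the previous interpolant's
prediction — so the interpolant reproduces every sampled value exactly
and the surplus doubles as a local error estimate.  Node identity is the
exact integer (level, index) pair per dimension, making nestedness and
deduplication exact; the dyadic coordinates themselves are exact in
binary floating point.

### Adaptive refinement

Levels 0–2 are sampled in full so the adaptive machinery starts from a
reliable picture.  Each subsequent stage applies, in order:

1. flag any current-stage node whose |surplus| exceeds the tolerance,
   defined as 1 % of the spread between the smallest and largest fitness
   sampled so far (the tolerance is recomputed every stage and can grow as
   the sampled range widens);
2. for unflagged nodes, flag if the interpolant's value at the node
   changed by more than 10× the tolerance over the previous two stages
   (|I_l(node) − I_{l−2}(node)|) — this catches places where the
   interpolant happens to cross the true value at the node but is wrong
   nearby;
3. if nothing is flagged, the surface is converged: stop
   (`tolerance-met`);
4. otherwise each remaining unflagged node is flagged with probability
   20 %, sparsely populating quiet regions against missed detail;
5. for each flagged node and each dimension, its two hierarchical
   children in that dimension (one child for boundary nodes) are added
   iff the node's error score times that dimension's max-normalised
   total-effect Sobol′ index still exceeds the tolerance.

The Sobol′ indices come from projecting the current interpolant onto an
orthonormal shifted-Legendre polynomial-chaos basis (uniform measure on
[0, 1]²) by tensor Gauss–Legendre quadrature — default total degree 8
with 12 points per dimension, ample for the smooth trends of a
piecewise-linear surrogate.  Total variance is the sum of squared
non-constant coefficients; a dimension's total-effect index sums the
squared coefficients of every tuple active in it, so interactions count
toward all participating dimensions.  Total-effect (rather than
first-order) indices are used for steering so a dimension active only
through interactions is never starved.  A zero-variance expansion yields
equal indices (no dimension preferred).  The error score used in rule 5
is the larger of the node's |surplus| and its interpolant change;
randomly included nodes pass through rule 5 like any other flagged node.

The run stops at `tolerance-met` or after building the level-10 stage
(`max-level`).  A single seeded random stream feeds the 20 % inclusion
rule, so runs are bit-reproducible; the simulator uses its own seed for
noise.

### Reading out the estimate

The final interpolant is probed on a dense 201×201 ζ grid; plateau-aware
local maxima are refined by pattern-search ascent, deduplicated at a
0.05 ζ separation, and reported if within 50 % of the best fitness — the
method must surface secondary high-likelihood regions (multiple
scatterers, or the characteristic double band discussed below), not just
the global maximum.  The best pair is imaged and returned with the
ranked candidates, the node count and the termination reason.

## Synthetic scan simulator

The simulator emulates scans of the layered phantom at 2D slice scale.
Each trace superposes:

- one echo per scatterer: the pulse delayed by τ(antenna, centre) and
  attenuated by reflectivity/L² (one-way distance L in mm) — spherical
  spreading; any monotone decay would do, this one is physical;
- a strong skin echo at the antenna-to-skin round trip with fixed
  amplitude 0.05, two orders of magnitude above the scatterer echoes, so
  the suppression stage is genuinely exercised;
- an empty-scanner self-reflection present identically in target and
  calibration traces (cancelled exactly by calibration subtraction);
- additive white Gaussian noise, seed-controlled, with RMS equal to
  `noise_level` times the RMS of the noiseless traces (fixture default
  1 %, a mildly noisy but essentially clean simulation).

The excitation is the derivative of a Gaussian with σ = 1/(2π·4 GHz) ≈
39.8 ps, placing the spectral peak near 4 GHz.  Echoes are placed so the
pulse's *positive peak* sits at the round-trip delay: the raw derivative
pulse is zero at its centre, so DAS sampling at the exact delay would
read zeros at the true scatterer position; aligning the dominant lobe
with the arrival makes the forward model consistent with plain amplitude
summation.

The canonical fixtures use ε_i = 2.5 (canola-oil interior), ε_s = 25, a
100 mm phantom with 2 mm skin, and 20 antennas on a 52 mm circle:
`single_scatterer` (10 mm scatterer at (25, 0) mm), `two_scatterers`
(10 mm scatterers at (25, 15) and (5, 15) mm) and `scatterer_plus_gland`
(scatterer at (17.68, 17.68) mm plus a 40 mm central gland).

### What the simulator does and does not show

Because reconstruction inverts the same straight-ray delay model the
simulator uses, passing tests demonstrate the *estimation machinery* —
fitness behaviour, sparse-grid interpolation, adaptive economy,
Sobol′-steered dimensional adaptivity, end-to-end localisation — under
controlled conditions.  They do not demonstrate robustness to the
physics the simulator omits: full-wave scattering, refraction, frequency
dispersion and loss, antenna patterns, mutual coupling, or realistic
skin-response variability.  Measured scans will show broader fitness
ridges and noisier surfaces than the fixtures do.

On the fixtures the recovered interior permittivity is systematically a
little high (typically 2.9–3.4 for a true 2.5, occasionally higher under
unlucky noise draws).  Two effects drive this upward bias.  First, the
bilobed pulse produces the characteristic *double band* in the fitness
surface: a slightly slower assumed speed aligns the echoes' negative
lobes at the scatterer position almost as coherently as the true speed
aligns the positive ones.  Second, at higher assumed permittivity a
fixed time window maps to fewer millimetres, so responses are
geometrically smaller and the area term A rewards them.  The same
mechanisms are why delay-based estimates track the real part of the
refractive index, n′ = √((√(ε′² + ε′′²) + ε′)/2), rather than ε′
itself — estimates sit at or above the true permittivity.  The skin
estimate is reported but not trusted: a 2 mm shell contributes a few
picoseconds of delay, the fitness is nearly flat in ε_s, and its Sobol′
index is correspondingly small.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| tolerance fraction | 0.01 | surplus threshold, as a fraction of the sampled value spread |
| change factor | 10 | multiplier on the tolerance for the interpolant-change rule |
| random inclusion | 0.2 | probability of flagging a quiet current-stage node |
| non-adaptive levels | 0–2 | full grids sampled before adaptivity starts |
| max level | 10 | hard stop (7169 full-grid nodes in 2D) |
| search box | ε_i ∈ [1, 12], ε_s ∈ [2, 70] | unit square maps onto this box |
| pixel size | 1 mm | reconstruction grid spacing |
| PC order / quadrature | 8 / 12 per dim | chaos degree and Gauss–Legendre points |
| pulse σ | 39.8 ps | derivative-of-Gaussian width (4 GHz spectral peak) |
| fixture noise | 0.01 | trace-RMS-relative white-noise level |

All are configurable via `EstimatorConfig`, `GridSpec`,
`PermittivityBox`, `Pulse` and the YAML `RunConfig`.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at the
fixture scale: 20 antennas, 1001-sample traces (5 ps over 5 ns), 1 mm
pixels (~7200 masked pixels), maximum grid level 10.  An adaptive run
samples a few hundred to ~1000 nodes and completes in seconds on one
core; the recovery check repeats it over five noise seeds.

## Known limitations

- Straight-ray, lossless, non-dispersive propagation; no refraction.
- The skin filter assumes near-identical skin responses across
  neighbouring antennas (true for the centred circular fixtures, only
  approximately true for real anatomy).
- The estimator optimises two parameters; the grid/PC machinery is
  written for general dimension, but tie-breaking choices (probe grid,
  maxima separation) are tuned for d = 2.
- The skin permittivity is weakly identified by design of the physics,
  not by a fixable flaw in the search.
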