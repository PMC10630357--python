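# Methods

`sixpackholo` implements the computational side of six-pack holography
(6PH) with three-wavelength hierarchical phase unwrapping: a single camera
frame multiplexes six off-axis interference channels — three illumination
wavelengths (692, 532, 490 nm) times two laterally shifted fields of view
(FOVs) — from which six complex wavefronts are reconstructed, combined
into synthetic-wavelength phase maps, and hierarchically unwrapped into
low-noise optical-path-delay (OPD) maps of optically thick transparent
samples.

## Signal model

An off-axis channel writes the object field E(x) onto a tilted reference
plane wave at carrier frequency f:

    I(x) = a^2 |E(x)|^2 + b^2 + 2ab Re[E(x) exp(i 2pi f . x)]

In the 2D Fourier plane this puts the cross-correlation (CC) term
`a b E^(nu - f)` at +f, its conjugate at -f, and the autocorrelation (DC)
terms at the origin. Six channels are summed with no cross terms between
non-matching pairs: in the instrument, crosstalk is suppressed by
wavelength separation and orthogonal polarization of the two FOV beam
sets, and the simulator takes that suppression as exact.

The object phase at wavelength lambda is `phi = 2 pi OPD / lambda`, with
`OPD = (n_s - n_m) h` — integral refractive-index contrast times physical
thickness. Phase maps are wrapped to [-pi, pi) throughout; this single
convention is enforced and tested (the matching fractional-cycle interval
is [-0.5, 0.5)).

## Carrier geometry (cycles per pixel)

All frequency bookkeeping is in cycles per camera pixel, so carrier
placement is independent of grid size. One CC disk has the coherent
radius

    r(lambda) = NA / (lambda M) * pixel_pitch

(0.0889 cycles/px at 692 nm for NA 0.42, M 40x, 5.86 um pixels). The
validator requires, with the common radius r: DC separation
|f_i| >= 2 r_max + r_i (the DC disk has twice the single-channel
bandwidth — a modeling choice the geometry makes necessary, since
|E|^2 doubles the band), pairwise separation |f_i - f_j| >= r_i + r_j,
conjugate separation |f_i + f_j| >= r_i + r_j (which encodes the
no-opposing-carriers rule, i = j included), and Nyquist containment
|f_i| + r_i <= 0.5.

The default layout places the six carriers on vertices of a 3x3 grid of
squares centered on the frequency origin. Of the sixteen vertices, the
inner four sit too close to the DC disk at the default NA and the eight
edge vertices form four antipodal pairs, so the only antipodal-free
six-vertex family uses four edge vertices plus two corners; we take all
six in the positive-f_y half-plane, the f_x < 0 half assigned to the
"left" FOV and f_x > 0 to the "right". The grid pitch is the midpoint of
the feasible interval implied by the four constraint families — fully
determined by the configuration, deterministic, and validated on
construction. The validator, not this particular choice, is the contract:
any user-supplied set that passes is accepted.

## Simulator

Phantoms are OPD fields on the object-plane grid:

- **Microchannel** — a cross-shaped air channel (n = 1.00) in PDMS
  (n = 1.39), height 7 um, hence OPD = -2730 nm inside; hard step edges.
  The horizontal arm spans the full width so the second FOV sees its
  straight continuation. Masks include `channel_interior` and
  `background`, eroded from the edges by one diffraction-limited
  transition width (ceil(1/r) pixels), because statistics taken across
  edge transitions measure the imaging model, not the sample.
- **Cell mosaic** — a seeded Voronoi tessellation emulating onion
  epidermis: interiors near -100 nm with smooth variation, boundary
  ridges of finite width with OPD varying smoothly between 1600 and
  3000 nm.
- **Flat field** — zero OPD (the background frame).

Each channel's field `exp(i phi)` is low-passed before interference. Two
points deserve emphasis:

1. **The low-pass acts on the field, not the phase.** The objective's NA
   limits the field spectrum; band-limiting the phase instead would let
   steep steps spray energy across the whole spectrum and into the other
   channels' CC disks.
2. **The default band is the common reconstruction bandwidth** (the
   692 nm cutoff, equal to the constant crop radius), not each
   wavelength's own cutoff. At the default NA the per-wavelength bands
   cannot be made pairwise disjoint by any six-carrier packing inside
   Nyquist (r_532 + r_490 = 0.241 cycles/px against a maximum pitch of
   0.186), and the constant-radius crop discards the excess band anyway.
   `field_band="per-wavelength"` restores the physically wider bands for
   leakage studies.

The low-pass disk edge carries a raised-cosine taper over the outer 35%
of its radius. This emulates the partially coherent illumination of the
instrument: an ideal hard pupil produces coherent Gibbs overshoot at step
edges strong enough to push the longest synthetic wavelength's phase
across the wrap boundary — an artifact the real source suppresses.

The two FOVs are modeled as pure horizontal rolls of the phantom by
+-fov_shift/2 (no rotation or scale change). Carriers are snapped to the
nearest DFT bin so fringes are grid-periodic and CC terms leakage-free;
reconstruction snaps identically. Noise enters as per-channel Gaussian
phase noise before band-limiting, plus optional Poisson shot noise and
Gaussian read noise in the electron domain; a single integer seed drives
independent streams for the sample and background frames. Frames are
scaled to fill the configured bit depth (8/12/16) and quantized; a
warning is raised if more than 0.1% of pixels are clipped from above.

What the simulator does **not** model: speckle, partial-coherence edge
profiles beyond the pupil taper (phantom edges stay hard), defocus beyond
a user-injected quadratic phase, polarization Jones calculus, and camera
fixed-pattern effects. Passing tests therefore demonstrate algorithmic
correctness under an idealized but self-consistent imaging model, not
instrument-level performance.

## Reconstruction

Per channel: FFT of the frame (origin-centered), crop the CC disk with
the **constant** radius matched to the 692 nm cutoff (identical lateral
resolution across channels, which hierarchical unwrapping needs),
re-center at zero frequency, refocus, inverse FFT, divide pixelwise by
the background-frame wavefront, optionally denoise.

- **Refocusing** uses the angular-spectrum kernel
  `exp(i 2 pi d sqrt(1/lambda^2 - |f|^2))` with evanescent components
  zeroed — exact scalar diffraction at these NAs, reducing to the
  paraxial Fresnel kernel for small angles. Distances are configuration
  inputs (typical use is below ~11 um; a 50 um sanity bound guards
  against unit mistakes). A sharpness-sweep autofocus helper (Tenengrad
  metric) is provided as a utility, not a contract.
- **Background division** removes any phase pattern common to sample and
  background frames (constant curvatures, alignment aberrations). Pixels
  where the background amplitude falls below 1e-3 of its maximum are
  zeroed and flagged in a validity mask rather than propagated as
  non-finite values.
- **Windowed-Fourier denoising**: Gaussian-windowed patches
  (sigma 6 px, patch 24 px, stride 6 px) are locally transformed;
  coefficients below 0.03x the patch maximum are zeroed; patches are
  accumulated with window-squared normalization, making threshold 0 an
  exact identity. The defaults were chosen so that on a seeded flat
  field with 0.2 rad phase noise the flat-region noise drops by more
  than half while a smooth noiseless field is preserved to better than
  0.01 rad. The filter is bypassable (`apply_wft=False`), and is
  bypassed in tests that need exactly traceable numerics.

## Synthetic wavelengths

For wavelengths l1 < l2, dividing the complex fields subtracts the
phases and yields the beat wavelength `Lambda_D = l1 l2 / (l2 - l1)`
(longer than both when l2 < 2 l1); multiplying them adds the phases and
yields `Lambda_S = l1 l2 / (l1 + l2)` (shorter than both). The phase is
read out with the two-argument arctangent and wrapped. From the three
channels of one FOV the nine-map ladder is, in descending order:
6206.67, 2300.90, 1678.61, 692, 532, 490, 300.77, 286.87, 255.07 nm.
The ladder keeps **unrounded** wavelengths internally — integer display
values (6207, 2301, ...) are rounding for humans; feeding them to the
cycle estimator corrupts thick-sample unwrapping. (The red+green
addition computes to 300.77 nm; its conventional display value of
300 nm is a rounding anomaly and the unrounded value is used.)

OPD-domain noise scales with the effective wavelength: a subtraction map
carries `sqrt(2) sigma Lambda_D / (2 pi)` of OPD noise for per-channel
phase noise sigma — amplified by the same factor the wavelength grew —
while addition maps are correspondingly quieter than the illumination
maps. Both scalings are verified on seeded simulations.

## Hierarchical unwrapping

The ladder trades these two currencies: long wavelengths avoid the 2 pi
ambiguity, short wavelengths have low OPD noise. The longest rung is
first unwrapped spatially with the reliability-sorting algorithm
(second-difference reliability, non-continuous paths; scikit-image's
`unwrap_phase` implementation), its global 2 pi-multiple offset fixed by
moving the median of a designated background region (or the whole image)
nearest zero. Then each transition from unwrapped phi'_n at lambda_n to
wrapped phi_{n+1} at lambda_{n+1} < lambda_n computes, pixelwise:

    m_n = phi'_n / 2pi              (real-valued phase order)
    F_n = phi_{n+1} / 2pi           in [-0.5, 0.5)
    I_n = round((m_n lambda_n - F_n lambda_{n+1}) / lambda_{n+1})
    phi'_{n+1} = 2pi (I_n + F_n)

`m_n` is deliberately the real-valued order, not its integer part: this
reading makes the step the standard rounding of the OPD difference, and
it is the reading that matches exhaustive integer search (the test
oracle) on every pixel. Ties round half away from zero. The output is
assembled as `2pi I_n + wrapped` so the wrapped part is carried
bit-exactly: wherever no whole cycle is added the rung reproduces its
input to the bit, and elsewhere it differs by whole cycles up to a few
ulp of float64. The result's OPD is guaranteed within
lambda_{n+1}/2 of the previous rung's.

The step is exact as long as the current map's OPD error stays below
half the next wavelength; if an OPD-noise estimate (sample std over a
user-designated flat region) exceeds that limit, the transition is
flagged in the result and surfaced prominently by the CLI — silent
cycle errors are the method's main hazard. The three-wavelength ladder
exists precisely to keep each gap small.

**Quality-masked seeding.** At a steep step the band-limited field
cannot follow the object phase (the maximum phase slope equals the
bandwidth), its amplitude collapses, and the phase inside the transition
is meaningless. On the hard-edged channel phantom this garbage ring
encloses the channel and lets a plain spatial unwrap carry a spurious
2 pi into the enclosed interior — which the ladder then faithfully
preserves as a whole missing wavelength. Phase maps therefore carry the
field amplitude as a quality channel, and the seed unwrap runs the same
reliability algorithm on a masked array (threshold 0.5x the median
amplitude), with low-quality pixels keeping their wrapped values. This
leans on the method's own premise: the longest rung is chosen so the
sample never wraps on it, so the identity branch is correct wherever the
spatial unwrap cannot be trusted. Masking is disabled by setting the
threshold to 0, and maps without an amplitude channel unwrap unmasked.

The final OPD map comes from the last (shortest) rung by default;
`final_rung` selects an earlier one. Any contiguous descending subset of
the ladder is accepted (e.g. two-wavelength mode for comparisons).

## Metrics and stitching

`phase_to_opd` applies `OPD = phi lambda / 2pi`; `implied_index_difference`
inverts `OPD = (n_s - n_m) h` for a known thickness (e.g. -100 nm over
140 um gives -7.1e-4); `region_stats` reports mean, std and accuracy
(100 mean/expected) over labeled masks; `diffraction_limit` is the
Rayleigh spot `1.22 lambda_max / NA` — the *maximal* (worst-case) spot,
hence the longest wavelength, 2.01 um at the defaults. `stitch_fovs`
places the two FOVs on a widened canvas, averages the overlap strip
(the display choice; no claim of optimality) and reports the std of the
left-right disagreement there rather than hiding it.

## Problem sizes and numerical choices

The test suite exercises 256x256 grids (one session-scoped hologram
pair) and the acceptance script 512x512, sizes at which every spectral
disk spans dozens of DFT bins while the full pipeline completes in
seconds. FFTs use numpy with origin-centered spectra; crops are disk
supports, never squares. All randomness flows from integer seeds through
`numpy.random.default_rng`; the sample and background frames use
distinct derived streams so their noise does not spuriously cancel in
the background division. Holograms persist as 16-bit TIFF containers
holding bit-depth-limited integers; float maps as 32-bit TIFF with JSON
sidecars; every run directory carries its config, manifest (config hash,
seed, versions) and reports.

## Known limitations

- Hard phantom edges plus coherent imaging make edge-transition pixels
  uninformative by construction; region statistics exclude one
  diffraction-limited width around steps, and recovered values within
  that band should not be interpreted.
- The crosstalk-free and equal-amplitude assumptions are taken from the
  instrument design rather than modeled; contrast imbalance can be
  injected via per-channel amplitudes but polarization leakage cannot.
- The spatial seed unwrap, even quality-masked, can still fail on
  samples whose OPD exceeds half the longest synthetic wavelength —
  that ambiguity is information-theoretic, not an implementation limit.
- The windowed-Fourier filter's defaults were tuned on the simulator's
  noise model; real-camera noise with structured components may need
  different settings (they are exposed in the run config).
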