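# Methods

This note documents the models, parameters and numerical choices behind
`axmwi`, and what the simulated studies do and do not show about real
axillary imaging.

## Tissue model

Every tissue is a single-pole Debye medium with a static-conductivity term,

    eps_r(w) = eps_inf + (eps_s − eps_inf)/(1 + j w tau) + sigma_s/(j w eps0)

under the e^{+jwt} convention (Im eps_r ≤ 0). The shipped library covers
skin, adipose tissue, muscle, and the surface layer and cross-section
(interior) of healthy and metastasised lymph nodes; the heterogeneous
healthy background of the axilla is dielectrically modelled after adipose
tissue. The relaxation constant is published only for skin (13 ps); we share
that value across all tissues (a relaxation time is not a magnitude, so it
is also excluded from the heterogeneity scaling below) and expose it per
tissue for sensitivity studies. At the 7.5 GHz centre frequency the
background permittivity is ≈ 4.28 − 0.83j, the metastasised node interior
≈ 37 − j·(large): the malignant contrast that makes radar detection
possible.

## Phantom geometry

The domain is 120 mm wide (the 80-mm antenna span plus 20-mm margins, the
span not being meaningfully extensible beyond the axilla) and covers a
100-mm-deep axillary region below the nominal skin surface, topped by a
6-mm air gap so antennas couple from air. Grid step dx = 0.5 mm (≥ 10 cells
per wavelength in the densest tissue at the upper band edge). Layers from
the top: skin (2 mm; optionally a sinusoidal surface with 1 mm amplitude
and 20 mm period — values chosen as a representative gentle undulation, the
shipped default when none is specified), optional 12-mm subcutaneous
adipose band (normal-weight adult), optional muscle band spanning depths
37–62 mm, and the heterogeneous background.

ALNs follow the parametric bean curve r(θ) = sin³θ + cos³θ (a closed
kidney-shaped lobe for θ ∈ [−π/4, 3π/4]), scaled so its longest chord
equals the 12-mm long axis, centred on its area centroid, and rasterised
onto the grid. A 1-mm outer ring carries the "surface" Debye parameters and
the interior the "cross-section" parameters. Nodes may not overlap the
skin, the muscle band or each other; the "deep node above muscle" study
therefore rests the bean tangent on the muscle surface (centre ≈ 33 mm)
rather than centring it inside the band.

Normal-tissue heterogeneity multiplies eps_inf, delta_eps and sigma_s of
background cells by one uniform factor in [0.95, 1.05] per 4-mm tile,
seeded per scenario (hash of the scenario name, overridable), leaving
tissue labels, skin, node, adipose and muscle cells untouched.

Two-node phantoms are placed by *surface gap*: the requested separation is
enforced between the rasterised mask edges, centred under the array, so the
centre distance (≈ long axis + gap) follows from the bean geometry.

## Forward solver

2D TMz FDTD with per-cell Debye media handled by an
auxiliary-differential-equation polarisation current, discretised
semi-implicitly (unconditionally stable for tau > 0; reduces to the
standard update for non-dispersive cells). Time step dt = S·dx/c0 with
S = 0.95/√2; double precision. Convolutional PML (10 cells, cubic-graded
conductivity, kappa = 1) terminates all sides, with material grids padded
into the layer by edge replication so the PML is matched to the adjacent
media; a free-space test puts the boundary residual near −100 dB. Antennas
are ideal soft point sources recording Ez at their own cell (monostatic),
placed in the air cell immediately above the local skin surface.

The excitation is a differentiated Gaussian with sigma = 1/(2π·7.5 GHz)
≈ 21.2 ps, which simultaneously yields the 7.5 GHz spectral peak, ≈ 150 ps
support and ≈ 9 GHz −3 dB bandwidth; it is delayed by 6 sigma so the record
starts quiet. The default time window is 4 ns (round trip to 100 mm depth
at the slowest tissue speed, with margin); the shipped scenarios use 3 ns,
which covers the round trip to the deepest imaging pixel (≈ 2 ns along the
domain diagonal at the background speed) plus the calibration offset and
integration window. A single all-air reference run provides the incident
waveform (position-independent in a homogeneous reflection-free domain),
subtracted from every channel so the artifact-removal stage faces the skin
response specifically.

## Artifact removal

*Average subtraction* removes the across-channel mean waveform (computed
via deviations from channel 0, so identical channels give an exactly zero
residual). *Adaptive filtering* fits, per channel, 2J+1 FIR taps on each of
the other channels by least squares over an early-time window and subtracts
the filtered prediction over the whole record. Defaults: J = 5,
fit window = the first 400 ps (incident support doubled for the skin round
trip plus 100 ps margin), ridge = 1e-3 scaled by trace(AᵀA)/n_taps so the
regularisation is scale-free; ridge = 0 falls back to a minimum-norm
solution. These defaults are choices — the published description of the
adaptive algorithm does not fix the window or filter length — and all are
exposed in `ArtifactConfig`.

## Beamforming

Delays assume one effective propagation speed v = c/√4.28 ≈ 1.45·10⁸ m/s
(real background permittivity at 7.5 GHz). Channel-ranked weights are
linear in the per-pixel distance rank (shortest distance → largest weight,
ties share averaged ranks), normalised to sum to the channel count so that
uniform distances recover the unweighted beamformer exactly. The
integration window defaults to the 150-ps pulse support, starting at the
delayed sample; energy is squared per time sample and accumulated. The DMAS
pair sum uses ((Σa)² − Σa²)/2, verified against the brute-force double loop.
Fractional delays use nearest-sample lookup by default (dt ≈ 1.1 ps makes
interpolation immaterial; a linear-interpolation flag exists). The imaging
grid matches the phantom pitch (0.5 mm) and covers the region below the
skin.

**Range calibration.** The mapping from the simulation clock to geometric
delays involves the pulse's internal delay and the skin transit, neither of
which the beamformer should hard-code. The scenario runner therefore
calibrates a single time offset against a known reference target — a
1.5-mm disk of eps_r = 30 at 20 mm depth in a clean uniform phantom — by
imaging it with DAS at zero offset and converting the peak's depth bias to
time. This is the standard radar range calibration; one offset per
acquisition configuration is reused across all scenarios.

## Metrics

SCR and SMR compare the maximum energy inside the truth region (mask
dilated by a 2-mm margin) to the maximum, respectively mean, energy
outside; with several nodes, each node's clutter region excludes the other
nodes' regions. MMR compares metastasised and healthy node maxima. FWHM is
the *full* width of the half-maximum response, averaged over the two grid
axes through the peak with linearly interpolated crossings (the metric's
name says full width; descriptions sometimes read as a half-width — we
implement the name). LE is the distance from the peak (searched in the
node's Voronoi cell when several nodes are present) to the true centre.
Two nodes count as *distinguishable* when the two highest
mutually-separated local maxima exist and each lies within half the node's
long axis (6 mm) of its centre. All metrics are invariant to global map
scaling.

## Problem sizes and determinism

The shipped studies use the full 16-antenna, 0.5-mm configuration
(240×212-cell phantoms, ≈ 2700 time steps per channel); a complete scenario
— 17 FDTD runs, two artifact methods, four beamformers, metrics — takes
≈ 15 s on one CPU with the numba-compiled kernels, and the six-point
two-node separation sweep a little over a minute. All randomness is the
tile heterogeneity, seeded per scenario; fixed-seed reruns are
bit-identical, and the on-disk FDTD cache is keyed by the phantom content
hash so warm reads equal cold runs exactly.

## What the simulations do and do not show

The phantoms reproduce the *study conditions* of the simplified 2D axilla:
layered tissues, mild heterogeneity, bean-shaped nodes with published
dielectric values. They do not model 3D geometry (2D line sources overstate
both scattering strength and aperture coherence), anatomically realistic
axilla shapes, antenna feeds and mutual coupling, or measurement noise.
Passing the shipped studies shows the processing chain behaves correctly
under the stated contrast mechanism — not that a physical system would
reach the same numbers.

One finding deserves emphasis: in the two-node separation sweep, a ghost
peak appears a few mm below the pair's midpoint once the surface gap drops
to ≈ 7 mm. Re-running the pipeline on the *linear superposition* of two
single-node acquisitions (minus the background run) removes the ghost, so
it is the physical inter-node multiple-scattering echo (extra one-way path
≈ the centre distance, ≈ 120 ps, mapping ≈ 9 mm deeper), not a processing
artifact — strong node contrast in 2D makes it comparable to the weaker
node's own peak. Under the strict two-peak / each-LE ≤ 6 mm predicate this
limits the shipped system's cross-range resolution to 9 mm; under the
weaker "fail only when both nodes are mislocalized" reading the limit is
5 mm, since one node remains well localized throughout.

## Open design choices

Where the underlying study leaves details unstated, this package chooses
once and documents: the bean-curve parametrisation and the sinusoidal-skin
amplitude/period (above); heterogeneity scaling applied jointly to the
three Debye magnitudes; the shared 13-ps relaxation time; the adaptive
filter's window/length/ridge; the linear rank-weight rule; the 150-ps
integration window starting at the delayed sample; nearest-sample delays;
the single effective speed; the point-reflector range calibration; the
2-mm metric margin. Each sits behind a configurable parameter.
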