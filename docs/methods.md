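# Methods

`ulm3d` is a simulation and processing toolkit for 3-D ultrasound
localization microscopy (ULM) with a sparse 2-D array.  It covers the whole
chain: design of a density-tapered spiral sparse aperture, synthesis of
microvessel-phantom data, 3-D plane-wave beamforming with coherent
compounding, SVD/ASAP clutter suppression, sub-voxel microbubble
localization, nearest-neighbor velocity tracking, and resolution metrics.
This note records the models, the parameters that matter, and the design
choices made where the problem was genuinely open.

## Sparse-array design

The probe model is a 32 x 35 matrix of 300 x 300 um elements at 3.7 MHz in
which rows 9, 18 and 27 (1-based) are unavailable for wiring, leaving 1024
usable elements.  Two complementary 256-element apertures are selected by

1. generating 256 seeds of a density-tapered Fermat spiral: azimuths advance
   by the golden angle (137.5078 deg), radii are placed by inverting the
   cumulative distribution of the target areal density r w(r), where w is a
   50%-Tukey taper over the 5.2-mm aperture radius.  The quantile of seed n
   is n/N, so the first seed sits at the center.  The construction is fully
   deterministic;
2. snapping each seed, in generation order, to the nearest free grid
   element (ties broken by lower row, then lower column);
3. repeating the snap with the first aperture's elements excluded to obtain
   the second aperture.  The union holds 512 distinct elements and never
   touches the blank rows.

The inverse-CDF radial placement reaches the same *statistical* density
target as published spiral-design optimizers without reproducing any
particular fabricated element list; reproducing a specific probe is a
non-goal.

### Beam patterns and grating lobes

The one-way array factor is evaluated on direction cosines and normalized
to its value at the steering direction.  For the fully gridded 35-row
pattern, the 9-row periodicity of the blank rows predicts a grating lobe at
arcsin(lambda / 2.7 mm) = 8.6 deg; the numerical pattern puts the highest
secondary lobe at 7.8 deg.  Two conventions exist for quoting its
amplitude:

* relative to the *actual* main lobe (32 live rows): 18.3%;
* relative to the *fully populated* 35-row reference response: 16.8%.

We quote both; the grating-lobe check uses the full-grid reference, the
convention under which the customary "about 17%" figure is reproduced.
The grating-lobe search excludes the main lobe and the near-in sidelobe
skirt of the finite aperture by searching only beyond half the predicted
first grating angle (4.3 deg); the first sidelobe of the 10.5-mm aperture
(3.1 deg, 22%) is a sidelobe, not a grating lobe.

### Transmitted field

The transmit-field simulator is an ideal point-source superposition: each
element radiates the imaging pulse delayed by the plane-wave steering law
and attenuated by 1/r.  No baffle or element-directivity term is included
(element directivity is a non-goal).  Snapshots are normalized to their own
maximum.  At 15 mm depth the trailing edge waves of the 512-element
aperture sit about 22 dB below the wavefront, comfortably under the -14 dB
level expected of a usable plane wave at that depth.

## Acquisition model

Nine plane waves steered over {-10, 0, +10} deg in both lateral directions
are fired at a PRF of 4500 Hz and compounded coherently into volumes at
500 Hz.  The imaging pulse is a Gaussian-windowed 3.7-MHz sinusoid whose
envelope FWHM spans three carrier periods.  The medium defaults to water at
25 C (Marczak sound-speed polynomial, c = 1496.7 m/s), giving a wavelength
of 404.5 um.

Delay-and-sum beamforming uses the two-way delay law (plane-wave transmit
delay referenced to the array center plus return distance), linear
interpolation on the analytic (Hilbert-transformed) channel signal, and no
receive apodization — the taper is built into the sparse layout.  Voxels
default to lambda/4 = 100 um.  Transmit delays in the RF synthesizer and
the beamformer use the same convention by construction, so a point
scatterer beamforms back to its true position within one voxel; the
simulated PSF of the full 512-element aperture at 25 mm has FWHMs of
roughly 870 x 870 x 615 um (x, y, z).

## Microvessel phantom

Two 200-um-diameter tubes are twisted into a double helix about an axis
along y at 25 mm depth, 10 mm long, with a 5-mm helix pitch.  Within
+-2.5 mm of the center the helix radius equals the tube radius, so the
centerline separation is exactly one tube diameter (the tubes are in
contact); toward the ends the radius flares smoothly to 0.5 mm so the tubes
separate at the inlets, where tube-width measurements are made on an
isolated tube.  Flows are laminar and opposing, with mean velocity 11 or
44 mm/s (peak = twice the mean, zero at the wall).

Microbubbles arrive at each inlet as a Poisson process (default
4.5 bubbles/s per tube) and ride the parabolic profile at a fixed radial
offset and azimuth.  Two population parameters deserve comment:

* **Tracer focusing** (`radius_fraction = 0.75`): injected radial offsets
  are uniform over a disc of 75% of the lumen radius.  Deformable
  scatterers in laminar tube flow migrate away from the wall, and a tracer
  column narrower than the lumen is what super-resolved width measurements
  of this kind of phantom actually show; a strictly wall-to-wall uniform
  distribution would also leave bubbles creeping indefinitely at the
  no-slip wall.
* **Destruction** (`destruction_prob = 5e-4` per transmitted pulse, nine
  pulses per volume): at 4500 Hz insonation most bubbles are destroyed
  within a fraction of a second, which thins the slow near-wall population
  and empties the outlet ends, as high-PRF insonation does in practice.

Both values were chosen, together with the injection rate, so that the
default fast-flow run localizes on the order of 1.5 bubbles per volume,
the operating density of the experiments this toolkit models.

### Image formation

Two models are provided:

* **PSF surrogate** (fast, default): each bubble stamps a separable
  Gaussian with FWHMs (793, 772, 499) um — the measured point-spread
  function of the modeled probe — scaled by its log-normal scattering
  amplitude.  Each stamp carries a random polarity per bubble and frame.
  This is deliberate: a bubble moving a substantial fraction of a
  wavelength between volumes returns echoes of essentially independent
  phase, so the slow-time mean of its complex beamformed signal is zero.
  A strictly nonnegative surrogate would instead accumulate a static
  occupancy pedestal along the vessels that the clutter filter would
  remove, imprinting ghosts; the random polarity restores the correct
  slow-time statistics in a real-valued volume.  Static clutter (wall
  echoes; speckle concentrated near the tube walls, default amplitude 0.5
  of a nominal bubble) is shared by both apertures; white noise (sigma
  0.005) is drawn independently per aperture.
* **RF synthesis** (for end-to-end verification): linear single-scattering
  echoes per transmission and element, beamformed per aperture by the DAS
  chain above.  On few-bubble scenes the two models localize the same
  bubbles within one voxel.

## Clutter suppression and dual-aperture combination

Each aperture's sequence is reshaped into a Casorati matrix
(voxels x frames) and its leading singular components removed.  The default
cut `svd_low = 1` reflects the in vitro situation: with zero-mean bubble
signatures, the static wall echo is the single dominant component, and
removing further components begins to eat moving-bubble energy (removing
two visibly biases localizations outward by ~15 um in the contact region).
The implementation removes the leading band by partial eigendecomposition
of the frame Gram operator, which keeps long sequences cheap; the
filter satisfies kept + removed = input exactly, and the singular spectrum
conserves Frobenius energy.

The two aperture sequences are combined by acoustic sub-aperture
processing: voxelwise sqrt(|<A conj(B)>_w|), the square-rooted magnitude of
the zero-lag slow-time cross-correlation over a short window (default
2 frames).  Common bubble signal survives; independent electronic noise
averages out of the correlation.  With independent per-aperture noise at
the configured level and a 4-frame window, the measured SNR gain is about
3 dB, inside the 2.9-5.1 dB range expected for this combination.

## Detection and localization

Candidate voxels are those within 6 dB of a robust amplitude reference
(the median of per-frame maxima — insensitive to one unusually bright
bubble).  26-connected regions become detections.  The deliberately high
working threshold keeps only blob cores: at deep thresholds (-30 dB) the
PSF of a single bubble spans ~8x the tube separation, and the huge
low-amplitude skirt both fragments into spurious satellite components and
dominates a plain amplitude centroid.  Three position operators are
available: full-region amplitude-weighted centroid, the default
`core_centroid` (centroid of voxels within 3 dB of the component peak,
`core_level = 0.7`), and a separable paraboloid apex fit.  Sub-voxel
accuracy of the centroid on noise-free Gaussian blobs is better than 0.05
voxel at lambda/4 sampling.

Two region-volume gates follow, both expressed relative to the analytic
volume of the Gaussian-PSF level set at the same relative threshold
(a closed-form ellipsoid):

* regions larger than 2x the PSF volume are discarded as multi-bubble
  echoes (the published rule);
* regions smaller than 5% of the PSF volume are discarded as
  threshold-boundary flicker — a genuine microbubble echo cannot be much
  smaller than the system PSF.

## Tracking and velocity mapping

Detections in consecutive frames are paired greedily by ascending Euclidean
distance inside a search window of 100 mm/s / frame rate, one-to-one.  A
candidate whose above-threshold echo volumes deviate by more than 50%
(normalized by the earlier frame; a symmetric option exists) is skipped, so
the track falls to the next-closest size-consistent candidate.  Pair speed
is displacement x frame rate, signed by the y-component (the flow axis);
signed speeds are averaged per cell on a 20-um grid for velocity maps.  On
unambiguous instances with up to five bubbles the greedy assignment equals
the exhaustive minimum-total-distance matching.

## Resolution metrics

Profile widths use linear interpolation between the samples straddling the
level, with plateau ties broken by the plateau centroid.  Two headline
measurements, and how they are estimated at reduced acquisition length:

* **Super-resolved tube width.**  0.5-mm sections of the isolated tube
  ends are projected onto the plane orthogonal to the local tube axis,
  histogrammed at 20 um, lightly smoothed (1-bin Gaussian), and measured as
  the FWHM of the in-plane maximum-intensity profiles.  Because every
  bubble holds one radial offset for its whole transit, a single section of
  a short run sees only a handful of independent offsets; the sections of
  both tubes' ends are therefore pooled in tube-local coordinates before
  measuring.
* **Opposing-flow separation.**  Every velocity sample in the contact
  region is projected onto the local inter-tube axis at its own axial
  position, and the separation is the distance between the
  velocity-weighted centroids of the positive- and negative-flow lobes.
  Per-slab extremum profiles (also provided, `peak_to_peak_separation`)
  need many more samples to stabilize than a reduced run provides.

## Problem sizes, determinism, and expected numbers

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical configurations give byte-identical
outputs.  The default desk-scale run processes 600 volumes (1.2 s of
acquisition at 500 Hz) on a 2.6 x 11 x 2.6 mm grid of 100-um voxels in
about 30 s; the system-level checks run 3000 volumes (half of the modeled
6-s fast-flow acquisition) in about two minutes and 3 GB.  At 3000
volumes the super-resolved tube width lands in the 140-175 um range and
the lobe separation of the touching 200-um tubes in the 160-225 um range
across phantom realizations (the tubes' centers are exactly 200 um apart);
the remaining scatter is dominated by the finite number of distinct bubble
transits, about 25 per tube, and shrinks with acquisition length.

## What the phantom does and does not emulate

Emulated: the phantom geometry and opposing laminar flows, the probe's
measured PSF, bubble-density and destruction behavior at high PRF, static
wall clutter common to both apertures, independent per-aperture noise, and
slow-time phase decorrelation of moving scatterers.  Not emulated:
nonlinear bubble oscillation and shell dynamics, attenuation and phase
aberration, speed-of-sound heterogeneity, element directivity and
crosstalk, probe or tissue motion, and beamforming artifacts beyond the
linear point-target model.  Passing tests therefore demonstrate the
correctness and resolution behavior of the processing chain under the
modeled physics, not the hardware performance of any physical probe; the
measured hardware quantities (PSF FWHMs, 18-um localization precision,
ASAP gain band, diffraction-limited Doppler widths) are represented by
property bands, not point reproductions.
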