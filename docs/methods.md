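# Methods

`tntsim` couples a desk-scale physical model of tissue nanotransfection
(TNT) at the sciatic-nerve surface with the outcome measures used to score
nerve regeneration: motor unit number estimation (MUNE) from incremental
stimulation, muscle torque and grip metrics with a recovery percentage, and
fluorescence quantification of nerve cross-sections. This note records the
model, its assumptions, the tunable parameters, and the numerical and
design choices, in the package's own terms.

## Electro-quasi-static field model

### Geometry

The chip–nerve interface is rasterized as a 2-D vertical cross-section on a
regular grid (default 100 × 100 cells over 120 µm × 120 µm, i.e. 1.2 µm
cells). From top (cathode side) to bottom (anode side): a conductive
reservoir band (default 12 µm) standing in for the microchannel/reservoir
compartment; a silicon plate of the nanochannel depth (11 µm) pierced by
nanochannels (0.9 µm wide, default 20 channels at 6 µm pitch); conical
needles (4 µm base, 4.5 µm height) rasterized as a staircase of rows of
decreasing width, with the channel lumen continuing through the cone core;
and nerve tissue below. Sub-cell features round to the nearest cell; a
channel that rounds to zero cells is a hard resolution error rather than a
silent omission. The microchannel dimensions (150 µm × 185 µm) are
validated against the wafer thickness (200 µm) but are not resolved in the
raster — at this window size the microchannel acts only as a well-conducting
series path, which the reservoir band captures.

A stated fraction of nanochannels conducts (default 65%). Exactly
`round(open_fraction × n_nanochannels)` channels are opened, sampled
uniformly without replacement from a seeded generator, because the real
devices clog stochastically and no fixed pattern is known. Blocked lumens
take the insulator conductivity.

The nerve-tissue domain used for outcome statistics is the lower-triangular
half of the grid (row ≥ column) intersected with tissue-labelled cells.
The triangular option (default on) reflects the wedge geometry of the nerve
under the chip edge; a rectangular tissue slab is available by switching
`triangular_tissue` off. The triangle orientation is configurable since
nothing pins it physically.

### Potential solve

Each pulse (default 200 V for 10 ms, 10 pulses; a 100 ms variant is
selectable in the protocol config) is long compared with dielectric
relaxation, and membrane impedance is taken as effectively infinite for
passive current flow, so the model solves the steady conduction problem
∇·(σ∇φ) = 0 once per pulse. Discretization is a flux-conservative
finite-difference scheme with harmonic-mean face conductances — the
standard choice for sharply contrasting conductivities, since it makes the
face flux exact for a series pair of materials. Boundary conditions:
Dirichlet rows for the electrodes (bottom row at +V, the positive electrode
under the nerve; top row at 0 V, the reservoir electrode) and zero-normal
flux on the side walls. The reduced symmetric M-matrix system (~10⁴
unknowns) is solved by sparse LU by default; Jacobi-preconditioned
conjugate gradients is available (`method="cg"`, default relative residual
1e-8, 50 000 iteration cap). The relative residual is always verified and a
failure raises with the residual attached. Rounding-level excursions beyond
the electrode potentials are clamped so the discrete maximum principle
holds exactly.

Default conductivities (config-exposed): saline lumen and reservoir
1.4 S/m, nerve tissue 0.5 S/m, silicon/nitride and blocked lumens
1e-12 S/m. An internal floor of 1e-15 S/m keeps the operator positive
definite for pathological inputs.

### Field magnitude and smoothing

`field_magnitude(phi)` is the central-difference gradient (one-sided at
edges). For heterogeneous media the pipeline instead uses
`field_magnitude(phi, sigma)`: the conduction field |J|/σ reconstructed
from the same harmonic-mean face fluxes the solver conserves. The two
coincide exactly in homogeneous media; across a conductor/insulator
interface the plain gradient straddles the potential jump and reports a
large spurious field in the first tissue row, whereas the conduction field
correctly vanishes where no current flows. This is what makes "a fully
blocked chip porates nothing" an exact property rather than an
approximation.

The field map is then Gaussian-smoothed (default σ = 1 cell, reflective
boundaries; the width is a free parameter and is config-exposed) to stand
in for sub-grid spreading around channel mouths. The pipeline smooths in
normalized (masked) form over the conductive region only —
smooth(E·m)/smooth(m) — so the enormous dielectric field *inside* the chip
body cannot bleed into tissue cells. Constants on the mask remain fixed
points and σ = 0 is the identity in both forms.

## Membrane response

The induced transmembrane potential uses the steady-state Schwan relation
at its angular maximum, ΔVm = 1.5·E·r, with coupling radius r = 5 µm (a
cell-scale length; config-exposed). Membrane orientation is not tracked on
a 2-D grid, so all criteria act on magnitudes: |Vm| = |v_rest| + ΔVm with
v_rest = −70 mV. A cell porates where |Vm| ≥ 200 mV (the nanoporation
threshold magnitude; all thresholds inclusive). With the defaults this
inverts to a field threshold of 0.13 V / (1.5 × 5 µm) ≈ 1.73 × 10⁴ V/m.

Action potentials are bookkeeping, not dynamics: a cell whose
depolarization reaches the −55 mV threshold (15 mV above rest) fires
`floor(pulse_ms / refractory)` times per pulse (refractory 1 ms → at most
10 APs per 10 ms pulse), giving a hard per-train cap. Conduction velocity
(120 m/s) and sodium-channel density (600 /µm²) are carried in the
parameter set and reported for provenance but drive no equations here —
no coupling law for them is established at this level of description.

Transfection of porated cells is stochastic: each porated cell draws an
efficiency p ~ Normal(mean 0.6, SD 0.15; config-exposed) clipped to [0, 1]
and realizes delivery as Bernoulli(p). Draws are made in row-major order
over porated cells only, making maps bit-reproducible for a fixed seed.

Under the default protocol the whole tissue wedge exceeds the poration
threshold (the applied 200 V over a ~120 µm window gives ~10⁶ V/m fields),
so the porated fraction saturates at 1; the interesting structure appears
at lower voltages or low open fractions, and the voltage sweep used in the
tests exercises exactly that monotone regime.

## Electrophysiology metrics

* **CMAP amplitude** — baseline = mean of the pre-stimulus window (default
  5 ms); baseline-to-peak = max |deviation| and peak-to-peak = max − min in
  the response window (default 50 ms). Peak-to-peak on a densely sampled
  noisy trace carries a small positive extreme-value bias (the max/min of
  ~10³ noise samples); the tests bound it by the Gaussian extreme-value
  scale rather than pretending it away.
* **Average SMUP** — mean of successive differences between consecutive
  submaximal response levels. Whether the step from no response to the
  first response counts as an increment is ambiguous in common usage; the
  `include_zero_baseline` switch covers both conventions, and
  `smup_summary` also reports the telescoped (last − first)/n value.
  Negative differences (alternation noise) are floored at zero with a
  warning, keeping n fixed.
* **MUNE** = max CMAP (peak-to-peak) / average SMUP, reported real-valued
  with the rounded integer alongside. For noiseless identical-unit pools
  the estimate is exact by construction; for lognormal pools (CV 0.3) the
  ratio estimator carries a small upward Jensen bias (~2–5% at the default
  noise), visible in the stochastic-recovery test and acceptance output.
* **Torque** — twitch peak = max above baseline of a single-stimulus
  response; tetanic peak = max over the 1 s, 150 Hz train, with the
  plateau mean (final 200 ms) reported alongside.
* **Grip** — arithmetic mean of trials, warning when the count differs from
  the three-trial protocol.
* **Recovery** = 100 × treated / healthy-control, scale-invariant, values
  above 100 reported as-is.

## Image quantification

Z-stacks are combined by maximum-intensity projection. Thresholding is
manual, negative-control based (reference mean + k·SD, k = 3), or Otsu when
no reference exists; the automatic Otsu threshold is floored at the image's
own mean + k·SD so a signal-free channel (pure background) yields an empty
mask instead of having its noise split into foreground. Objects are
8-connected components of at least 4 px (speckle suppression); both
constants are arguments, since the original vendor-software settings for
such analyses are generally unpublished.

"Having / not having": NF components are axons; an axon is myelinated iff
its overlap with the MBP mask reaches 1 px (an overlap-fraction variant,
e.g. ≥ 10% of the axon's area, is selectable). The myelinated/unmyelinated
percentages partition the axon count, so they sum to 100 whenever any axon
exists; zero axons return flagged nulls rather than a division error.
Densities count components whose centroid lies inside the ROI polygon
(centroid-in-ROI prevents double counting across adjacent fascicle ROIs)
divided by the polygon area in mm². Capillaries are CD31 components
retained only when they overlap DAPI (≥ 1 px). Coassociation reports
double-positive components (marker A overlapping marker B, DAPI-confirmed
when a DAPI mask is supplied) as a percentage of a denominator that must be
chosen explicitly — A components (default, e.g. lineage-reporter cells), B
components, or components of the merged mask — and is echoed in the result
because percentages with unstated denominators are not comparable.

## Synthetic data

Generators produce exactly the formats the analysis consumes and return
the truth they embedded.

* **Motor pools** — lognormal unit amplitudes (physiological right skew)
  with stated mean (default 0.2 mV) and CV; CV = 0 degenerates to identical
  units. Recruitment thresholds are sorted uniforms over the 1–10 mA
  stimulation range.
* **Increment series** — cumulative sums of the first k recruited units
  plus Gaussian measurement noise; full recruitment matches the CMAP
  generator's peak-to-peak by construction.
* **CMAP/torque traces** — a biphasic template normalized on its own
  samples so peak-to-peak equals the pool sum exactly; twitch transients
  and fusing 150 Hz tetanic envelopes (rise constant 50 ms, 0.5% ripple)
  renormalized so the sampled maximum equals the requested peak.
* **Nerve micrographs** — NF discs (radius 2–4 px), MBP annuli spanning
  radii (r−1, r+2] around the myelinated subset (guaranteeing ≥ 1 px
  overlap), CD31 rings (radius 5–7 px, 2 px wall) each carrying a 2 px DAPI
  nucleus in the wall (an endothelial nucleus), optional GFP co-labelled
  vessels and standalone GFP⁺/DAPI⁺ cells, free nuclei, and Poisson(2)
  background in every channel at foreground ~200. All objects are placed by
  seeded rejection sampling (10 000-attempt cap, packing prechecked)
  inside a rectangular ROI of exactly the requested area (default
  0.1 mm²), with separations large enough that thresholded components
  never merge — which is what makes the embedded counts exactly
  recoverable at default thresholds.

What the generators do **not** emulate: motor-unit alternation and firing
statistics, real EMG waveshapes, axon-diameter distributions and g-ratios,
staining heterogeneity, optical blur and bleed-through, or out-of-focus
structure. Passing the round-trip tests therefore demonstrates the
correctness of the bookkeeping and thresholding logic, not robustness to
real histology; on real images the manual/negative-control thresholds and
the overlap rule are the parameters a user must justify.

## Problem sizes and runtime choices

All tests and the acceptance script run on one CPU in seconds: the solver
grid is the default 100 × 100 (direct sparse solve ≈ 50 ms), Monte-Carlo
checks use 100 seeded replicates, image round trips use one 512 × 512
five-channel section plus fifty 256 × 256 sections. These sizes were chosen
to make every stochastic check stable at fixed seeds while keeping the full
suite fast enough to run on every change.

## Known limitations

* 2-D cross-section; no 3-D channel array effects, no Joule heating, no
  electrode electrochemistry, no pore-resealing kinetics or DNA transport.
* One quasi-static solve per pulse; membrane charging transients are not
  resolved (consistent with the high-membrane-impedance assumption).
* The field-to-Vm coupling radius collapses cell geometry and orientation
  into one scalar; absolute poration extents should be read as relative
  comparisons between protocols, not calibrated predictions.
* The Gaussian transfection-efficiency model is phenomenological; its mean
  and SD are free parameters.
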